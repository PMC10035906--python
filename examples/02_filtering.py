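"""Filter a dense network down to a drawable one and print the reports.

Starts from the complete graph on 250 sphere nodes (31125 links, weight =
1/distance), then applies the ECO density criterion (keep the strongest
round(3N/2) links, i.e. average degree 3) and a minimum-distance filter.
"""

from spatnetviz import eco_filter, min_distance_filter, top_degree_subnetwork
from spatnetviz.fixtures import complete_network

net = complete_network(250)
print(f"complete fixture: {net.n_nodes} nodes, {net.n_links} links")

eco_net, rep = eco_filter(net)
print(f"after ECO:        {rep.links_after} links "
      f"(kept the strongest {rep.links_after}/{rep.links_before})")

far_net, rep = min_distance_filter(net, d_min=1.0)
print(f"links with d > 1: {rep.links_after} links of the original "
      f"{rep.links_before} span more than a unit-sphere radius")

sub, rep = top_degree_subnetwork(eco_net, 50)
print(f"top-50 nodes:     {sub.n_nodes} nodes, {sub.n_links} links survive")

# ECO keeps round(3*250/2) = 375 links; because the weights here are
# inverse distances, those are exactly the spatially shortest links —
# ECO and the min-distance filter pull in opposite directions on this
# fixture, which is why they are applied to the same source network.
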