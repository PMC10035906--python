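# Methods

## Geometric model

A link between nodes S_i and S_j is confined to the plane through S_i,
S_j and a virtual reference point C. The construction:

1. **Chord frame.** M = (S_i + S_j)/2, u = (S_j − S_i)/d_ij. The
   elevation direction w is the component of (M − C) orthogonal to the
   chord, normalized. Using the orthogonal component rather than the raw
   C→M direction guarantees u ⊥ w, so the summit height h is exactly the
   point-to-chord distance and the right-angle constraint at the summit
   is well defined.
2. **Summit.** U = M + a₁·d_ij·w. Because w points away from C, U is
   always on the far side of M from C ((U−M)·(M−C) ≥ 0), producing
   concave, outward-bowing links.
3. **Control points.** With α = a₃π, d_S = a₄·d_ij/2, d_U = a₂·d_ij/2:
   B₁ = S_i + d_S(cos α·u + sin α·w), B₁′ mirrored at S_j;
   B₂ = U − d_U·u, B₂′ = U + d_U·u. Placing B₂/B₂′ along ±u realizes the
   fixed right angle between the summit handles and the U–M reference
   line.
4. **Sampling.** Two cubic Bezier pieces with control polygons
   (S_i, B₁, B₂, U) and (U, B₂′, B₁′, S_j), each sampled at
   `samples_per_half + 1` uniform parameter values and concatenated
   without duplicating U. The endpoints and the summit are written into
   the polyline exactly (no floating-point residue), so endpoint
   interpolation is bit-exact.

The pieces are cubic, not quadratic: each has two independent interior
control points, which a quadratic Bezier cannot represent, and the eight
presets are only reproducible with the cubic reading.

**Conventions chosen where the construction was open.** α is measured in
the link plane from the chord direction, rotating toward the summit side
(α = 0 departs along the chord, matching the Bell/Peak presets' a₃ = 0;
α = π/2 departs along w, matching Circle/Square's a₃ = 0.5). With a₄ = 0
the node control point coincides with the node, making a₃ inert — the
Default preset (a₃ = 0.38, a₄ = 0) exercises this deliberately, and no
warning is emitted. Contralaterality is enforced along the full reference
line (not only its vertical component).

**Degenerate inputs.** Coincident nodes are an error (such a link is not
drawable). If C falls on the chord line, the plane is undefined; the
frame falls back to the global vertical for w, and to the lateral x-axis
when the chord itself is vertical. Both fallbacks keep u ⊥ w and |w| = 1.

## Coordinates

Internal convention is y-up right-handed (x, y, z). Input CSVs default to
`xzy` order — the file's second column is depth, the third the altitude —
and are permuted once at import; no other module re-permutes. The CSV
dialect is comma-separated, `.` decimal, no header; a non-numeric first
row is rejected as a header rather than silently skipped. The JSON bundle
schema (`coordinates`, `matrix`, `labels`, `axis_order`) is defined by
this package.

Adjacency handling is strict by default — asymmetry beyond 1e-9 or a
nonzero diagonal is an error — with opt-in symmetrization. Rationale:
only undirected networks are supported, so silently coercing an
asymmetric matrix would hide user error.

## Filters

* **ECO density criterion**: keep the K = round(degree·N/2) largest-weight
  links, degree = 3 by default (the average-degree-3 property that defines
  the criterion). `round` is half-up (⌊x + 0.5⌋) so odd N is deterministic
  across platforms. Connectedness is *not* repaired; a warning is logged
  when filtering disconnects the graph.
* **Density**: strongest ⌈p·L⌉ links for a proportion p ∈ (0, 1], or
  exactly k links for an integer k.
* **Minimum distance**: keep links with Euclidean span strictly greater
  than d_min.
* **Top-degree subnetwork**: induced subgraph on the k nodes of largest
  unweighted degree (incident-link count, computed before removal) —
  link count, not strength, because the degree glyphs are defined on
  link counts.

Ties are always broken deterministically: equal-weight links by ascending
(i, j) index pair, equal-degree nodes by ascending index. All filters
preserve symmetry, the zero diagonal, and retained weights/coordinates.
Idempotence under a repeated identical parameter holds for ECO,
absolute-count density, minimum-distance and top-degree filtering;
proportional density is relative to the current link count, so composing
it twice compounds by design. The CLI applies filters in a fixed order —
node filter, then distance filter, then density/ECO — for
reproducibility.

## Scene and styling

Nodes are icospheres; links are polylines (*line* mode) or swept tube
meshes (*volume* mode). Tube sweeping places one ring of `tube_sides`
vertices per polyline point and parallel-transports the ring frame along
the curve — Frenet frames would flip at inflection points, parallel
transport cannot. End caps are triangle fans around a center vertex, so
the tube is watertight. Link radius is `scale / d_ij` clamped to
[r_min, r_max]; link color is the weight min–max normalized **over the
retained links** (what the viewer of the filtered network actually sees),
mapped through a matplotlib colormap; a constant-weight network maps all
links to the colormap midpoint. Degree bars are tubes from each node
along the direction away from C with height `bar_scale · degree`;
zero-degree nodes get no bar. Support solids (unit sphere, unit cube, or
a user OBJ/PLY mesh via trimesh) are transformed scale → rotation →
translation. The default camera looks at the barycenter from 2.5×
the bounding-sphere radius along +x. Scene construction contains no
randomness: identical inputs give bit-identical scenes.

## Export

**glTF 2.0** is written directly (single `.gltf`, embedded base64
buffer): one named mesh node per primitive (`node_12`, `link_3_7`,
`bar_4`, `support`), triangle meshes as mode TRIANGLES with uint32
indices, line-mode links as mode LINE_STRIP, one flat base-color material
per primitive. The generator string is constant and no timestamp is
written, so re-exports are byte-identical. Round-trip fidelity is tested
both with the package's own reader and independently with trimesh's glTF
loader.

**Raster** rendering is an offscreen software projector on the matplotlib
Agg backend: orthographic projection from the scene camera, primitives
painted far-to-near and faces depth-sorted within each mesh (painter's
algorithm; no z-buffer, which is adequate for mostly-convex scene
elements). The projection window is the padded bounding box of the
projected geometry, expanded to the image aspect ratio so scale is
isotropic; it is serialized to a JSON sidecar so a render can be
reproduced exactly. The default spec is 6000×3500 pixels at 96 DPI in
TIFF. DPI metadata goes into the TIFF resolution tags exactly; PNG pHYs
stores integer pixels-per-metre, so 96 DPI reloads as 96.012 — an
inherent quantization of the PNG format, not a bug. Node labels are never
rasterized. Line-mode strokes are drawn at one device pixel (72/dpi
points).

## Synthetic networks

The fixture generators emulate the demo families used throughout the
examples; all randomness flows through numpy's seeded PCG64 generator, so
a fixed seed reproduces a network bit-identically across platforms.

* `sphere_ba_network(n, m, seed)` — points area-uniform on the unit
  sphere (uniform azimuth, uniform cos-polar, avoiding polar clustering);
  topology by preferential attachment. The urn variant is self-contained:
  the first m nodes start isolated and seed the urn once each; every
  arriving node draws m *distinct* targets from the urn (endpoints are
  re-added after each link, so attachment is degree-proportional), giving
  exactly m·(n − m) links. Unit weights.
* `lattice_network(nx, ny, nz, p_extra, seed)` — integer grid,
  6-neighbourhood links, plus round(p_extra·L) random non-neighbour
  shortcuts. Link weight is 1 + mean elevation of the endpoints; the +1
  offset exists because grid elevations start at 0 and a weight of 0
  would mean "no link" in the adjacency encoding.
* `complete_network(n, seed)` — all pairs of n sphere points linked with
  weight 1/d_ij, so weight filters and distance filters act in opposite
  directions; n = 250 gives 31125 links.
* `random_geometric_network(n, radius, seed)` — uniform points in the
  unit cube, linked iff d_ij < radius with weight 1 − d_ij/radius
  (strictly positive on every link).

These fixtures share the statistical shape of real spatial networks
(fixed embeddings, distance-dependent connectivity, heavy-tailed degrees
for the preferential-attachment family) but none of their measurement
noise, geographic anisotropy or community structure; tests passing on
them validate the geometry, filtering and export machinery, not any
claim about a particular empirical dataset.

## Problem sizes and defaults

`samples_per_half` defaults to 32 (65 polyline points per link) as a
smoothness/cost compromise; `tube_sides` defaults to 8. The test suite
runs its property checks on 200 random fixtures of 3–25 nodes and 1000
random node-pair configurations, and renders one full-size 6000×3500
frame; the whole suite completes in well under a minute on one CPU.

## Known limitations

Directed networks, self-loops and sparse adjacency input are rejected,
not coerced. Edge bundling, crossing minimization and geodesics on
curved surfaces are out of scope — the method is deliberately a light
geometric alternative to those. The raster renderer's painter's
algorithm can mis-order mutually intersecting meshes. The ECO filter
does not repair connectivity. Interactive viewing (hover highlighting,
label pop-ups) is not provided; the glTF export is the hand-off to
interactive tools.
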