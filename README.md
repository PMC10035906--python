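# spatnetviz

3D visualization of **spatial networks** — graphs whose nodes occupy fixed
positions in physical space (brain connectomes, transport systems, airline
routes, sensor arrays). Conventional graph-drawing moves nodes around to
untangle links; for spatial networks the node positions *are* data, so
spatnetviz leaves every node exactly where the data puts it and instead
reshapes the **links** as smooth 3D curves whose geometry follows the
internode distance. Scenes export to glTF 2.0 (for Blender, three.js,
Unity, …) and to high-resolution TIFF/PNG renders.

It is a library first (`import spatnetviz`), with a thin `spatnetviz`
command-line tool over the same pipeline and narrative scripts in
`examples/`.

## The link model

Every link between nodes S\_i and S\_j lies in the plane spanned by the two
nodes and a virtual reference point **C** (default: the barycenter of all
node positions, optionally shifted vertically). With **M** the chord
midpoint and d\_ij = |S\_j − S\_i|, the link is a two-piece cubic Bezier
curve through a summit **U** on the C–M line, placed on the side of M
opposite C so links bow away from the network's center. Four
dimensionless coefficients control the silhouette:

| coefficient | controls | formula |
|---|---|---|
| a₁ | summit height | h = a₁·d\_ij |
| a₂ | summit handle length | d\_U = a₂·d\_ij/2, laid ⟂ to the U–M line |
| a₃ | departure angle at the nodes | α = a₃·π, measured from the chord |
| a₄ | node handle length | d\_S = a₄·d\_ij/2 |

The two cubic pieces have control polygons (S\_i, B₁, B₂, U) and
(U, B₂′, B₁′, S\_j). Eight named presets cover the canonical shapes:
Default (0.75, 0.5, 0.38, 0), Bell (0.75, 0.5, 0, 0.5),
Triangle (0.75, 0, 0, 0), Circle (0.5, 0.5, 0.5, 0.5),
Circle2 (0.9, 1, 0.8, 1), Square (0.5, 1, 0.5, 1), Peak (0.75, 0, 0, 1),
Straight (0, 0, 0, 0).

Two further conventions keep dense networks readable: link **radius** is
inversely proportional to d\_ij (long links are thin, so short ones stay
visible underneath), and link **color** encodes the connection weight.
Node degree can be shown as a bar pointing radially away from C, and the
**ECO density criterion** keeps only the strongest round(3N/2) links
(average degree 3) by default.

## Worked example

```sh
python examples/01_link_shapes.py
```

prints, for one link with d\_ij = 2 and C below the chord:

```
preset       a1   a2   a3   a4  height h  max rise  arc len
Default    0.75  0.5 0.38  0.0     1.500     1.500    3.740
Bell       0.75  0.5  0.0  0.5     1.500     1.500    3.809
Triangle   0.75  0.0  0.0  0.0     1.500     1.500    3.606
Circle      0.5  0.5  0.5  0.5     1.000     1.000    3.097
Circle2     0.9  1.0  0.8  1.0     1.800     1.800    5.359
Square      0.5  1.0  0.5  1.0     1.000     1.000    3.604
Peak       0.75  0.0  0.0  1.0     1.500     1.500    4.008
Straight    0.0  0.0  0.0  0.0     0.000     0.000    2.000
```

`height h` is a₁·d\_ij, the summit's elevation over the chord midpoint;
`arc len` shows how much path the curve adds over the straight chord
(exactly 2.0, the chord itself, for the Straight preset). The other
examples filter a 250-node complete graph (31125 links → 375 after ECO),
render a scale-free sphere network with degree bars to glTF + PNG, and
place a cube support inside a 3D lattice.

A full shell pipeline:

```sh
spatnetviz fixtures --kind sphere_ba --n 100 --m 2 --seed 7 --out net.json
spatnetviz render --bundle net.json --preset Peak --degree-bars \
    --gltf-out net.gltf --image-out net.tiff
```

The default raster export is 6000×3500 pixels at 96 DPI (TIFF); every
render also writes a JSON manifest of all resolved parameters and filter
reports.

## Input formats

* **Coordinates CSV** — one row per node, three numeric columns, no
  header. Axis order is `xzy` by default: column 2 is depth, column 3 is
  the vertical axis (pass `--axis-order xyz` for plain order).
* **Adjacency CSV** — N×N, symmetric, non-negative, zero diagonal.
  Directed networks are not supported; `symmetrize` averages A and Aᵀ if
  you need the coercion.
* **Labels CSV** — optional, one label per line.
* **JSON bundle** — one object with keys `coordinates`, `matrix`,
  optional `labels`, optional `axis_order`; written by
  `write_network_bundle` and the `fixtures` subcommand.

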