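# Methods

## Input model

One record per segmented cell or landmark object: sample id, a phenotype
label from a fixed per-run vocabulary, position (x, y, z) in micrometers,
nonnegative per-channel MFIs (columns prefixed `ch_`), optional morphology
(volume µm³, sphericity). Coordinates are continuous object centroids —
there is no pixel grid — and 2D sections are encoded with a constant z.
CSV (UTF-8, comma, `.` decimal, mandatory header) is the only interchange
format; phenotype gating happens upstream and must arrive as a column.
Landmark "spots" (e.g. vessel objects) carry no special status: they are
ordinary phenotypes, which keeps every downstream operation uniform.

## Neighborhoods

A neighborhood of radius r (default 30 µm) collects all cells within
Euclidean distance ≤ r of a center — distance in x–y only (cylindrical
window) when the sample's z thickness max(z)−min(z) is below r, otherwise
in x–y–z (spherical). Membership is a closed ball: a cell at distance
exactly r is a member, which makes brute-force oracle comparisons exact.

Raster centers form an axis-aligned grid with spacing r/2 per gridded
axis, anchored at the per-sample coordinate minima and extended until the
last center reaches or passes the maxima. Anchoring at the minima makes
the scan deterministic and translation-covariant; with spacing r/2 every
interior point of the bounding box is covered by at least four
neighborhoods in 2D, so neighborhoods deliberately overlap. For
effectively-2D samples the single z level is the sample's z midpoint.
Cell-centered mode instead places one neighborhood on every object of a
chosen phenotype. The center object itself is counted by default (it is a
member at distance 0 when the centers come from the same table;
`include_center=False` removes one exactly-coincident cell of the center's
phenotype, and for centers disjoint from the cell table the flag adds the
center's own phenotype and channel values).

Internally a k-d tree answers the range queries, but the contract is the
all-pairs brute-force result: counts match bit-exactly, summed MFIs to
1e-9 relative.

## Region discovery

Feature modes over the neighborhood count matrix (optionally extended with
the summed-MFI columns, off by default):

- `raw` — counts as-is;
- `composition` — each row divided by its total; all-zero rows stay zero;
- `standardized` — per-column z-score with the **sample** SD (N−1); the
  training means/SDs are frozen on the feature matrix so held-out samples
  can be projected. Zero-variance columns are set to 0 with a warning.

Empty neighborhoods carry no compositional information, so the clustering
pipeline drops all-zero rows (`NeighborhoodSet.nonempty()`) before
composition clustering; keeping ~1,000 coincident zero vectors (the
out-of-tissue raster margin) was observed to distort the cluster-count
selection by adding a zero-radius point mass.

Clustering is a 1-D chain SOM of NR nodes, batch-trained for 200 epochs:
each epoch assigns every row to its best-matching unit (nearest prototype,
ties to the lowest index), then moves each prototype to the Gaussian-
weighted mean of the rows, weighted by chain distance between the
prototype and the row's BMU. The kernel radius decays linearly from
⌈NR/3⌉ to 0 over the first 100 epochs; the remaining epochs are
nearest-only (Lloyd) steps, so the final prototypes are a locally optimal
vector quantization with SOM-ordered initialization. Prototypes are
initialized by sampling NR distinct data rows with the run seed; training
is deterministic given (data, NR, seed). A step ("bubble") kernel was
rejected because at NR=2 its initial radius spans the whole chain and
collapses both prototypes onto the global mean. Bitwise parity with any
particular SOM implementation is not attempted; the contract is clustering
quality (separable data are partitioned identically to k-means).

NR is selected by sweeping candidate counts (default 2–10, hard cap 50)
and taking the minimum of the Davies-Bouldin index of the SOM's own
labels, ties toward the smaller k. DB uses sᵢ = mean member-to-centroid
distance and dᵢⱼ = centroid distance; coincident centroids with zero
scatter contribute 0 (the 0/0 case), and if a sweep's SOM leaves a
prototype unused DB is evaluated over the occupied clusters. Region
indices are 1-based; manual annotation attaches composite labels (e.g.
"TZ+IFZ") without touching the indices, so merging is reversible.

## Spatial statistics

Cell-cell correlation is the Pearson r of per-phenotype counts across
neighborhoods, computed per sample and averaged (unweighted) over the
cohort; `pooled=True` concatenates samples instead. Scoping to a region
restricts to that region's neighborhoods; recomputing a region standalone
gives identical matrices. Zero-variance phenotypes yield missing entries
(never 0), excluded pairwise from the cohort mean. Significance uses
t = r√(n−2)/√(1−r²) on n−2 df, two-sided; |r| = 1 maps to p = 0. P-values
are reported unadjusted — the analysis is descriptive, and adjustment
belongs to the caller's testing burden (a Benjamini-Hochberg helper is
available in `statsmodels` if needed).

Pseudo-space sorts neighborhoods by Σ_c w_c f_c (negative weights pull a
phenotype leftward), ascending stable sort with the neighborhood index as
final tie-break, then smooths each phenotype's profile with an
edge-truncated boxcar (window in neighborhoods, default 50) and divides by
its own maximum. The boxcar is the minimal assumption-free kernel for a
user-defined smoothing amount; window 1 is the identity.

## Geometry

Surfaces are alpha shapes: Delaunay simplices with circumradius ≤ alpha
are kept; in 2D their union is a shapely polygon set (holes arise
naturally), in 3D the boundary is the set of triangular faces used by
exactly one kept tetrahedron. alpha → ∞ gives the convex hull. The default
alpha is twice the raster grid spacing (= the neighborhood radius), since
surfaces typically wrap neighborhood centers spaced r/2. Degenerate inputs
(collinear/coplanar) raise naming the degeneracy.

Signed distance: magnitude is the Euclidean distance to the nearest
boundary point (2D via shapely; 3D as the minimum point-triangle distance,
computed by orthogonal projection when the projection's barycentric
coordinates are valid, else the nearest of the three edge segments). The
sign is negative inside, positive outside, 0 on the boundary; 3D
containment uses crossing parity of a fixed ray against the face mesh, so
distances are measured to faces, not vertices. Boundary points count as
inside for gating. Nearest-object distances are exact k-d-tree nearest
neighbors; the proximal fraction is the share of cells within a cutoff
(20 µm default). RDP controls are uniform on the reference bounding box of
the plotted axes only (z is copied when constant) with all channels 0.

## Region networks and embeddings

Contact: neighborhood centers within `contact_radius` of each other (same
sample only, self-pairs excluded). The default radius 1.1·√2·(r/2) covers
the raster grid's 8-neighborhood with 10% float slack. Entry (i, j) of the
contact matrix is the percentage of region-i neighborhoods touching ≥ 1
region-j neighborhood; the matrix is directional because region sizes
differ, and the undirected rendering takes the max of the two directions.
Edges are kept when the percentage strictly exceeds the threshold, default
0.005% — a deliberately permissive published default (nearly any contact
qualifies) that is kept rather than "corrected". Empty regions give NaN
rows. Force-directed layout is presentation-only.

Embeddings are seeded wrappers: t-SNE (Barnes-Hut, Euclidean, perplexity
30, angle 0.5, exaggeration 4; requires ≥ 3·perplexity+1 rows), exact PCA,
and UMAP. PHATE is not provided.

## Synthetic tissue generator

Each compartment draws an independent homogeneous Poisson point process
per phenotype at intensity λ (cells/µm² in 2D) clipped to its geometry
(disk, annulus, box); overlapping compartments resolve later-wins, and
draws from earlier compartments are thinned where a later one covers them,
so every compartment interior is homogeneous at its own rate. Channel MFIs
are lognormal — bright (log-mean 4.0) on the phenotype's hallmark channel,
dim (1.0) elsewhere, log-SD 0.3. Ground truth is a position → label
oracle, so neighborhood centers can be truth-labeled, not just cells.
An expected count above 10⁷ is refused.

`ln_preset()` is a 1,000 µm-diameter disk: six follicles (radius 120 µm,
centers on a 340 µm ring) with λ_B = 4×10⁻³, λ_T = 4×10⁻⁴,
λ_DC = 2×10⁻⁴; a central T zone (λ_T = 3×10⁻³, λ_DC = 1×10⁻³,
λ_B = 2×10⁻⁴); a 100 µm medullary ring (λ_Mac = 2×10⁻³,
λ_DC = 1.5×10⁻³, λ_T = 3×10⁻⁴). These rates are a desk-scale caricature
(≈3–4×10³ cells per tissue, ≈4.5×10³ raster neighborhoods at r = 30 µm)
with the density contrasts that define the real compartments (B:T = 10
inside follicles). The generator deliberately omits cell-cell spatial
interaction, segmentation error, staining spillover, and irregular organ
outlines — so passing tests demonstrate that the pipeline recovers planted
compartmental structure under Poisson noise, not that it is robust to
real-world imaging artifacts.

## Problem sizes and numerics

Default validation runs use ≤ 2,000-cell oracle instances, ~3.5×10³-cell
synthetic tissues, and 10-seed repetitions; these sizes give stable
statistics (Poisson CVs of a few percent) while keeping a full run in
minutes on one core. Counts are compared bit-exactly against oracles,
summed intensities at 1e-9 relative, correlation matrices at 1e-12
absolute, DB at 1e-9 against an independent implementation; analytic
disk/sphere distances carry a 0.02 boundary-sampling tolerance. Known
limitations: no spatial autocorrelation correction in the correlation
analysis (neighborhoods overlap by construction, so p-values are
optimistic and should be read comparatively), no geodesic distances, no
adaptive neighborhood radii, and 2-D SOM grids are out of scope.
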