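# Methods

## Problem setting and model

`figprov` treats scientific-figure reuse detection as media provenance
analysis over a corpus of documents. The unit of analysis is the *panel* — an
independent sub-image of a compound figure — because whole figures mix
informative content with legend letters, arrows and diagrams that match
trivially across honest papers. Five panel types are distinguished
(microscopy, blots, body imaging, graphs/plots, flow cytometry); graphs and
plots are excluded from provenance analysis by default since analytically
generated charts from different data are often visually near-identical and
would flood the analysis with false links. Panels are compared pairwise, only
across documents: reuse *within* one document is normal practice and carries
no evidence of fabrication.

The pipeline makes two passes over each candidate pair. A cheap global
descriptor prunes the quadratic comparison space to a per-probe queue; an
expensive local verification then decides whether two panels actually share
pixel content and how much.

## Stages and their parameters

**Figure extraction.** PDFs are parsed by walking the object stream for
embedded image XObjects (FlateDecode and baseline-JPEG streams); pages are
never rendered, so vector overlays are ignored and the extracted rasters are
bit-faithful to what was embedded. Rasters with a side below 64 px are
discarded as logos/icons. The minimum-size filter and the treatment of
multi-page figures are deliberately configurable; there is no canonical
convention for either.

**Panel detection.** Three interchangeable backends: curated annotation
boxes (a JSON schema recording bbox, type and optional reuse-group label per
panel), a whitespace-gutter splitter (recursively split on the widest run of
≥ 10 fully-near-white rows/columns, threshold 240/255, then tighten each leaf
to its content bounding box; panels come back untyped), and a `model` hook
for an externally trained detector (loading weights is the caller's problem;
training is out of scope). Boxes are clipped to the figure and duplicates
with IoU > 0.8 collapse to the higher-confidence box. Panel ids are assigned
in reading order (by box center, top-left to bottom-right) over *all*
detected boxes before filtering, so ids are stable under changes to the
allowed-type set.

**Global description.** The default `hash` backend is deterministic and
weight-free: luma (ITU-R BT.601) is resized to 64 × 64, the magnitudes of the
12 × 12 lowest-frequency 2-D DCT coefficients form the structure part, and
8-bin per-channel RGB histograms (weighted 0.5) form the color part; each
part is L2-normalized, then the concatenation is. DCT magnitudes are exactly
invariant to horizontal/vertical mirroring (flips only change coefficient
signs) and stable under rescaling and recompression; histograms are
flip-invariant by construction. A `conv` backend accepts any callable
wrapping a pretrained network for users who want learned descriptors; it is
optional so that nothing in the package requires a download.

**Retrieval.** Exact cosine scan over all stored vectors of the query's
panel type, excluding the query's document, top-K with K = 400. Ties in
cosine break by ascending panel id — the corpus scan must be reproducible
across platforms. The in-memory matrix scan is the intended scale here; an
approximate vector index would slot in behind the same interface but is out
of scope.

**Pixel verification.** SIFT keypoints (scikit-image) on the grayscale
panels, brute-force descriptor matching with cross-check and Lowe's ratio at
0.75 (raw brute force floods the robust fit with false pairs), then a RANSAC
projective fit with a 3 px reprojection threshold, at most 10,000 trials
(stop probability 0.9999) and a fixed sampling seed. A pair is consistent
when ≥ 20 correspondences survive the fit — counted *after* robust
refitting. SIFT is not mirror-invariant, so when the direct attempt fails
the probe is flipped horizontally and re-matched; success on the retry sets
the `mirrored` flag (vertical flip is available behind a config flag). If
fewer ratio-test survivors exist than the inlier bar, the fit is skipped
outright — the bar is unreachable — which keeps full-corpus scans fast.
Degenerate fits (non-finite or singular homographies, collinear samples) are
inconsistencies, not exceptions.

**Content-sharing score.** For a consistent pair, each side's score is the
area of the convex hull of its verified interest points divided by the
panel's area, with mirrored-frame points mapped back first and hull points
clipped to the panel bounds. Fewer than three non-collinear points score 0.
Coordinates are treated as continuous positions in `[0, w] × [0, h]`, so a
hull constructed from the panel's corners scores exactly 1. A known property
of the estimator: through the pixel pipeline the hull of real keypoints is
strictly interior to the panel, so a fully reused panel's score saturates
around 0.8–0.9 rather than 1.0, while score *ratios* between the two
directions are preserved (the planted half-area crop yields a ratio of 0.50
to three decimals). The 1% suspicion threshold is far below either effect.

**Queue loop.** Per probe: initialize with the top-K retrieval, examine
FIFO, record both directional scores of every consistent pair, and when
either direction reaches the 1% threshold enqueue the candidate's own top-L
(L = 40) same-type neighbours (still excluding the probe's document,
deduplicated against everything already queued). The loop stops when the
queue empties or 300 candidates have been examined; skipped
(already-processed) pairs do not consume budget. A single processed-pair
registry is shared across all probes, so each unordered pair is verified at
most once per corpus scan and the final table does not depend on probe order
(probes run in sorted id order regardless, for reproducibility). The
threshold is inclusive (≥ 0.01) everywhere it appears.

**Graphs.** Undirected edge weight between two panels is the larger of the
two directional scores — full reuse of a crop should weigh 1.0 no matter
which side is the probe. Connected components at the 1% threshold are the
shared-content groups; each component's maximum spanning tree (Kruskal;
equal-weight ties prefer the lexicographically smaller edge) is the
provenance graph. The highest-degree node is surfaced as the hub — the
natural entry point of an investigation. Document aggregation counts
suspicious *panel pairs* per document pair (counting pairs rather than
distinct panels keeps the matrix additive with the panel-level table), links
documents with a count ≥ 1 and repeats the component/MST construction on the
integer weights.

**Metrics.** Truth links are derived from annotated category labels as all
unordered cross-document within-category pairs. Content pairing is link
precision/recall over predicted vs. annotated links; content grouping
matches predicted groups to categories greedily by largest overlap (ties:
group index, then label; each side used once; unmatched groups/categories
contribute zero terms), with NP = overlap / |predicted group| and NR =
overlap / |category|; content classification is set precision/recall of the
suspicious set (all ids appearing in any provenance graph). Each task is
summarized by the harmonic mean of its two numbers, defined as 0 when both
are 0 (and 1 when both sides of a task are empty — nothing to find, nothing
falsely found). Greedy overlap matching is a deliberate choice over an
optimal assignment: it is the transparent rule an analyst can audit, and the
two differ on about a quarter of adversarial small partitions, a discrepancy
documented in the test suite's definitional oracle. NP divides by the
predicted group's size — i.e. it is a precision — which is the reading
consistent with the question the metric answers.

## The synthetic corpus generator

The generator emulates the needle-in-a-haystack structure of a paper-mill
investigation: `n_documents` (default 30) with `n_mill_documents` (default
5) mill documents, one figure of four panels each, and reuse groups (default
three, of sizes 3/3/4 in microscopy, flow cytometry and body imaging) whose
edited copies are placed in distinct mill documents by cycling, so the mill
cluster is fully covered and every within-cluster document pair shares
content directly. Panel types are procedural: blob-field micrographs,
low-entropy blurred band blots (intentionally hard — few keypoints, like
real Western blots), smooth nested-gradient body imaging with organ-like
blob texture, sparse scatter flow cytometry on white (≥ 60% white pixels),
and axes-plus-bars charts. Texture densities were calibrated once so that
every non-blot type survives all pairwise combinations of the default edit
chains at the 20-inlier bar with margin; blots deliberately do not.

Default edit chains stay inside the robustness envelope the pipeline is
designed for: rescale 0.5–2.0, JPEG quality ≥ 60, mild recolor and noise,
crop to 64% area, rotation ≤ 15°, horizontal flip, splice onto a clean
background. Every copy's exact chain parameters are recorded in
`truth.json`, alongside group members, image- and document-level link sets,
suspicious sets and the full per-panel annotation (the same schema the
annotation ingest backend consumes). A `crop50` preset plants the canonical
pair — a source panel twice as wide as tall and its left-half crop — whose
directional scores are exactly 1.0 and 0.5 under a spanning hull.

What the generator does *not* emulate: real biological texture statistics,
staining variability, figure-assembly artifacts (sub-panel borders, inset
labels, annotation arrows), or adversarial edits aimed at defeating SIFT
(heavy blur, strong projective warps, generative re-synthesis). Passing the
synthetic recovery suite therefore demonstrates that the pipeline's
machinery is correct and robust across the stated edit envelope — not that
its recall on real corpora matches the synthetic one; real blot-heavy
corpora in particular will sit far below it.

## Numerical and determinism notes

Every stochastic component is seeded: corpus generation from the spec seed,
the RANSAC sampler from a config seed, and all tie-breaks (retrieval order,
MST edges, probe order) are lexicographic. Two runs from the same spec and
seed produce byte-identical corpora, tables, graphs and reports, which the
test suite asserts. Hull areas use Qhull with the last digit rounded (12
decimals) so that exact geometric constructions score exact values.
Problem sizes in the test suite — 30-document corpora, 50-pair matching
sweeps, 100-graph oracle comparisons — were chosen to exercise every code
path at full parameter defaults (K = 400, L = 40, cap 300) while keeping a
complete run in the low minutes on one CPU.

## Known limitations

* Blot recall is intentionally poor at the 20-inlier bar; lowering the bar
  trades directly against false positives on low-entropy panels.
* The PDF walk reads embedded rasters only: vector figures, CCITT/JBIG2
  streams and encrypted files are not supported (encrypted files fail
  loudly).
* The whitespace-gutter splitter assumes panels sit on a light background
  with clean gutters; figures with dark backgrounds or touching panels need
  the annotation or model backend.
* Scores compare verified point hulls, not segmented regions: a small
  spliced fragment inside an otherwise unrelated panel yields a small score
  on both sides, bounded below by the 1% threshold for detectability.
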