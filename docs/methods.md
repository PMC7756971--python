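# Methods

## Scope and model

`formulanet` operates downstream of peak picking and alignment: its inputs
are aligned per-mode feature tables (feature id, m/z, retention time, one
peak-height column per sample), MS/MS spectra keyed to feature ids, ELSD
peak tables of the single-herb traces, and a sample manifest declaring
which run is the formula, which is a single-herb extract (with its w/w
proportion in the crude mixture and a plot color), and which is a blank.
Raw-file conversion, peak picking, deconvolution and alignment are out of
scope by design; so is the construction of in-silico fragmentation
libraries (a user-supplied library is consumed instead; a 40-entry built-in
toy library with synthetic spectra ships for demonstrations).

## Molecular network

Spectral similarity is the modified cosine in its GNPS-compatible form:
intensities are square-rooted and the weight vector scaled to unit
Euclidean norm; candidate fragment pairs are those within the fragment
tolerance either directly or after shifting by the precursor-mass
difference; a one-to-one assignment is chosen greedily by descending weight
product. The greedy choice (rather than an optimal assignment) reproduces
the reference tool's behavior and costs O(p² log p); on analogue-style
spectra with well-separated peaks the greedy score provably equals the
optimum, and the tests assert exact agreement with a maximum-weight
assignment oracle on 200 such pairs, plus the one-sided bound (greedy ≤
optimum) on adversarial random spectra. Symmetry under operand swap is
enforced by canonically ordering the two spectra before the greedy loop, so
tie-breaks cannot depend on argument order.

Edges require cosine ≥ 0.7 and ≥ 6 matched peaks (fragment tolerance
0.02 Da). The matched-peak rule is implemented as an inclusive `≥ 6`
because that is the parameterization the reference pipeline uses for "more
than six"; a strict reading is available via `strict_matched`. An edge
survives only if each endpoint is within the other's top-50 surviving
neighbors by cosine (ties broken by lower feature id, for determinism).
Clusters are connected components of size ≥ 2, numbered 1-based by
descending size with ties broken by smallest member id; singletons carry
the sentinel −1. No maximum component size is applied.

## Specificity

The specificity share of a feature for herb *i* is its height in herb *i*
over the sum of its heights across all herb samples, ×100. Formula and
blank heights are excluded from the denominator. "Detected" means height
> 0 after alignment; no extra height floor is imposed. The division is done
before scaling by 100 so a single-source feature is exactly 100%.

Features are first reduced to those detected in the formula and not
attributable to blanks. The blank rule defaults to *relative*: a feature is
blank-derived when its maximum blank height is ≥ 0.5 × its maximum herb
height; a strict *any-detection* mode is available. The relative rule is a
package choice — alignment tables do not state one — and 0.5 keeps
genuine herb components that bleed faintly into blanks.

Node threshold 90% and cluster threshold 75% are both inclusive; features
reported in the 90–94% band count as specific, which fixes the convention.
Cluster means are unweighted arithmetic means over members present in the
specificity table — i.e. formula-detected, blank-filtered nodes — since
averaging over herb-only nodes would describe material absent from the
preparation; a flag (`all_nodes`) widens the average if wanted. Report
percentages round half-up (23/80 → 29%, not banker's 28%), one decimal for
feature shares, nearest integer for cluster-level summaries.

## ELSD integration

Peaks with area ≥ 0.004 µV/s (inclusive) are kept and labeled herb code +
rank, rank 1 being the largest area, ties broken by earlier retention time.
Attachment to HRMS features uses an RT window of ±0.1 min; candidates
default to the source herb's *specific* feature set (matching the selection
intent; `all` widens to every formula feature), and the candidate with the
highest height in the source herb wins, ties by lower feature id. Optional
nominal-m/z corroboration (±0.5 Da against a QMS trace) and a manual
override map (label → feature id, mirroring manual curation) are supported;
overrides always win. Unmatched peaks are reported as "not detected in the
formula", not errors, and the three marker failure categories
(non-specific, not-in-formula, retained-by-abundance) are reported
independently without forcing them to be disjoint.

## Markers and signatures

PI and NI features of one molecule are paired by neutral mass ([M+H]⁺ minus
a proton vs [M−H]⁻ plus a proton, 1.007276 Da) within 10 ppm and RT within
0.05 min, 1:1 by smallest combined normalized distance. A marker is
`specific` when its worst-mode share is ≥ the node threshold in every mode
where it was detected; single-mode detections are judged on that mode and
flagged rather than hidden. An abundance-override option relabels the
top-n sub-threshold peaks per herb `non_specific_retained` — the situation
where a formula's most abundant component is kept as a marker despite
imperfect specificity — instead of silently passing them.

Signature categories: (1) dominant herb and ≥ 1 anchor; (2) anchor but no
dominant herb, members restricted to nodes specific to the anchor's herb;
(3) dominant herb, no anchor, ≥ 1 species/genus/family-level annotation
among members. Assignment is mutually exclusive in that order. Bar
chromatograms collapse members co-eluting within 0.02 min (in-source
adducts/fragments) to the highest-formula-height one.

## Annotation

Molecular formulae are enumerated over CHNO within bounds (C ≤ 60,
H ≤ 120, N ≤ 10, O ≤ 30 by default) inside a ppm window of the neutral
mass, keeping integer ring-and-double-bond equivalents in [0, 40]
(even-electron neutral molecules); candidates rank by absolute mass error.
The enumeration is exhaustive within bounds and is tested against a literal
brute-force oracle on small bounds. Library matching restricts entries to
the precursor window (0.005 Da), scores with the same modified cosine,
floors at 0.2 and keeps the top 6. Chemotaxonomic re-ranking is a stable
sort by taxon depth (species > genus > family > none) then cosine, a pure
permutation that never alters scores. Inside a cluster holding an anchor,
candidates of the anchor's compound class are promoted ahead of the rest;
co-members are labeled `Co-<anchor>-k` by ascending retention time (the
numbering convention is a package choice). Cross-mode candidate consistency
is reported, not enforced.

## Synthetic data

The generator emulates the study design: each herb contributes analogue
families (default 4 families × 5 members per herb, 10 herbs) whose spectra
share an 8-peak fragmentation template plus 2 member-specific peaks —
within-family modified cosine is ≥ 0.89 by construction and cross-family
similarity is negligible, so network clusters should reproduce the family
partition exactly. Herb heights are concentration × per-metabolite,
per-mode ionization factor (lognormal, σ = 0.3) × multiplicative lognormal
noise (CV 0.1 by default); formula heights are the w/w-weighted sum of the
herb signals with their own noise draw; the w/w proportions are exact
29ths matching a typical ten-herb recipe (printed rounded: 3.4%, 6.9%,
3.4%, 6.9%, 20.7%, 10.3%, 13.8%, 6.9%, 20.7%, 6.9%). ELSD areas are
concentration-proportional and ionization-independent. Six ubiquitous
metabolites span all herbs (singleton spectra), and blank contaminants
appear in blank + formula only.

Each family's first member is the planted marker: concentration 5–10 versus
0.1–0.5 for other members, so its ELSD area (0.02–0.04 µV/s) clears the
0.004 floor with a margin the 10% noise cannot erase, while non-marker
areas stay below it. Retention times sit on a 0.05-min global grid with
herbs interleaved, so same-herb metabolites never co-elute within the ELSD
matching window and no two features fall inside the in-source collapse
tolerance; ±0.01 min jitter keeps the grid from being perfectly regular. A
fraction of non-marker members (15%) is emitted in one ionization mode
only, to exercise the single-mode marker path. Everything derives from one
seeded generator, so a fixed seed gives byte-identical bundles.

What the generator does **not** emulate: isotope patterns, adducts beyond
protonation, chromatographic peak shapes, retention drift between runs,
correlated (matrix) noise, and shared metabolites between subsets of herbs
other than the all-herb ubiquitous class. Passing recovery tests therefore
demonstrates the correctness of the statistics and plumbing under the
stated mixture model, not robustness to real-data artifacts such as
misalignment or in-source fragmentation richness.

## Problem sizes and numerical choices

The default synthetic study has ~200 metabolites per mode (≈400 features,
≈21k spectrum pairs per mode), which keeps a full workflow run in seconds;
the acceptance script uses this size throughout. Degenerate inputs are
defined: empty spectra are rejected at normalization; a feature with zero
herb signal has undefined shares and is excluded from specific counts and
cluster averages; clusters with no scored member are dropped with a
warning; an empty candidate window in formula assignment returns an empty
list. All rankings specify tie-breaks (feature id, RT, entry id) so every
output is a pure function of its inputs; CSV reports are written with fixed
float formatting and sorted rows, and figures use a fixed SVG hash salt
with no timestamps, making reruns byte-identical.

## Known limitations

Greedy peak assignment can undercut the optimal matching on pathological
spectra (dense peaks at spacing comparable to the tolerance). ELSD-to-HRMS
attachment assumes a shared retention-time scale; only a global window (and
an optional linear shift via overrides) is provided, not retention
alignment. Formula enumeration covers CHNO only — sufficient for the
phenolics, terpenoids and alkaloids targeted here, but not sulfated or
halogenated metabolites. Share uncertainty is not modeled (no replicates),
and cluster means are unweighted, so a cluster's dominant herb can be
driven by low-intensity members.
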