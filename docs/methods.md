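# Methods

## Signal model and assumptions

A DIA run is modelled as an ordered list of centroided scans: each
acquisition cycle holds one MS1 full scan followed by one MS2 scan per
precursor isolation window. Charge 1 is assumed for precursors and
fragments; multiply charged species that mimic the neutral loss are a known
false-positive class and are deliberately not corrected, only reviewable in
the export. Isotopologue envelopes and ESI adducts (+Na, +K, +NH4) are not
annotated automatically; the exported columns (m/z, RT, area of both peaks)
are sufficient to do this downstream.

The detection chemistry is the glycosidic-bond cleavage of protonated
2′-deoxynucleosides under CID, losing neutral C5H8O3. The constant is
recomputed from standard atomic monoisotopic masses (116.0473 Da to 4
decimals) rather than hard-coded, and the built-in nucleoside table (dG, dA,
dC, dT, 5-me-dC, N6-me-dA, 8-oxo-dG) is derived from molecular formulas the
same way.

## Dataset split

MS2 scans are keyed by their isolation window — (center, width) rounded to
4 decimal places — rather than by position within the cycle, so a dropped
scan cannot shift the window assignment of later scans. Window intervals
are half-open [lo, hi): a precursor sitting exactly on a boundary belongs to
the upper window only, which makes membership deterministic and
double-counting impossible. Retention times are normalised to seconds on
read for both dialects. Profile-mode spectra are rejected rather than
centroided in-house: the PIC tracker assumes centroids, and silent
centroiding would hide a data problem.

## PIC extraction

Tracking is greedy and deterministic. Per scan, open traces claim unclaimed
centroids in order of accumulated trace intensity (highest first); each
takes the centroid nearest in ppm to its running intensity-weighted mean m/z
(ties toward higher intensity, then lower m/z). The weighted mean, not the
last point, is the matching reference — it damps centroid jitter. A trace
survives `max_gap` consecutive missing scans (default 1) and must reach
`min_points` (default 5, configurable down to 3) to be emitted.

The mass tolerance is relative (default 10 ppm), with an absolute-mDa
option; Orbitrap-class mass error is mass-proportional, so ppm is the
default. MS1 and MS2 datasets may use separate parameter sets but default
to identical values.

## Zero-area-filter peak detection

The detector correlates the PIC intensity trace with a zero-sum kernel: a
Gaussian of width `kernel_sigma_scans` (default 2 scans) minus its own mean
over a ±3σ support. Any zero-sum symmetric kernel annihilates constant
baselines; the Gaussian variant is the matched filter for Gaussian elution
profiles. At trace edges the kernel is truncated to the available support
and re-centred to zero sum, so constants map to zero everywhere.

Candidate apexes are local maxima of the response above
`snr_threshold × σ_resp` (default threshold 5). The response noise scale
σ_resp is the trace's point-noise sigma — estimated robustly as
MAD(first differences)·1.4826/√2, which cancels smooth peak structure —
propagated through the kernel's L2 norm. A response-trace MAD was
considered and rejected: on short traces where one peak plus the kernel
support covers most points, the entire response is signal and that estimate
saturates, suppressing obvious peaks. The difference-based estimate stays
calibrated there and is equally scale-covariant (scaling intensities by c
scales both signal and threshold by c, leaving decisions unchanged). Its
known limitation: on ~25-point pure-noise traces the small-sample MAD
occasionally dips low and admits a false positive (~0.5% of such traces);
the support and shape filters remove most of these.

Candidates must show a rising-then-falling raw profile, and their support —
points strictly between the flanking raw minima (strict descent, so a flat
baseline bounds a peak instead of joining it) — must reach
`min_peak_points`: default 5 for reliable identification, floor 3 for
poorly resolved peaks.

Refinement smooths the trace with a centred moving average
(`smooth_window_scans`, default 5, odd) and sets boundaries to the nearest
interior local minima flanking the apex; an apex without an interior
minimum on one side is clamped to the trace end and flagged. Quality flags:
`noisy_surroundings` when another smoothed maximum ≥ 50% of the apex lies
within twice the peak width of either boundary; `irregular_shape` when the
refined segment of the smoothed trace is not unimodal (more than one
interior maximum). Area is the trapezoidal integral of raw intensity over
RT (counts·s), invariant under RT offset.

## Neutral-loss matching

For each window, every MS1 precursor peak with mean m/z inside the window
is paired against every fragment peak from that window's MS2 dataset whose
mass difference lies within 3× the loss tolerance of 116.0473 Da; the wider
enumeration envelope means near misses appear in the output as rejected
candidates (`loss_out_of_tol`) instead of vanishing. Acceptance requires
all of:

| filter | default | reject reason |
|---|---|---|
| loss error (ppm of precursor m/z) | ≤ 10 ppm | `loss_out_of_tol` |
| apex RT difference | ≤ 6 s (≈ one DIA cycle) | `rt_mismatch` |
| RT-extent overlap / shorter extent | ≥ 0.5 | `low_overlap` |
| precursor area | ≥ 10⁴ counts·s | `low_area` |
| peak shapes | both unimodal | `bad_shape` |
| precursor m/z in window | — | `wrong_window` |

The co-elution thresholds (6 s, 0.5) are declared defaults of this package:
co-elution is standard for neutral-loss pairing but its numeric
operationalisation is an open design choice. One precursor matching several
fragments (or vice versa) keeps all pairs, ranked by absolute loss error
and annotated with the multiplet size; pruning is left to review, which is
what the reject-provenance columns in the CSV are for.

## Synthetic runs (what the generator does and does not emulate)

The generator emulates the acquisition geometry (default: nine m/z-20
windows over 190–370, 3.5 s cycle — a plausible Orbitrap cycle time, since
no canonical value exists — over a 240 s run) with Gaussian elution
(σ = 5 s), per-centroid m/z jitter (2 ppm), a constant per-species baseline
(50 counts) sampled in every scan, additive intensity noise (σ = 300
counts), and Poisson chemical-noise centroids (mean 8/scan, log-normal
intensities) uniform in m/z. Fragment apex amplitude is 40% of the
precursor's (CID efficiency is not modelled; the value is configurable per
species). The default manifest spikes the four unmodified nucleosides as
dominant species (amplitude 5×10⁵–2×10⁶ counts, as in a real digest, which
exercises the area filter and multiplet handling), modified nucleosides and
random adduct-like pairs up to ten true species (2×10⁴–2×10⁵ counts, i.e.
≥ 60× the noise sigma), and ten decoys whose precursor−fragment difference
is kept ≥ 0.03 Da away from the neutral loss. Species are mutually
separated by ≥ 0.05 Da so each yields a distinct PIC, and no cross-pairing
of any precursor with any other species' fragment reproduces the loss.

Not emulated: isotope envelopes, ESI-adduct satellites, structured
(correlated) chemical noise, peak tailing/fronting, retention drift and
saturation. Passing recovery tests therefore demonstrates the correctness
of the pipeline's logic and its noise margins under idealised peak shapes,
not performance on real chromatography; on real data the shape filters and
manual review carry more weight.

Runs are written as minimal centroided mzXML (64-bit, uncompressed) or
mzML; generation is byte-reproducible from the seed.

## Numerical choices and degenerate inputs

- Tie-breaks in PIC claiming: nearest ppm, then higher intensity, then
  lower m/z — total order, so extraction is deterministic.
- Exact m/z collisions within a generated scan are separated by one float
  ULP to preserve the strictly-ascending invariant.
- An empty dataset yields an empty PIC list; a PIC shorter than the kernel
  support is filtered with truncated kernels; a single-point integration
  range has zero area and the peak is discarded.
- A constant trace produces an identically zero response; the detection
  threshold is floored at 10⁻⁹ × the trace maximum so float dust is never
  "detected" while noiseless fixtures still work.
- The whole pipeline is deterministic given (input file, configuration):
  repeated runs are byte-identical, with wall-clock times only in the log.

## Problem sizes

The bundled recovery study uses 20 simulated runs of 690 scans each
(≈ 69 cycles × 10 scans); detection-oracle and noise-false-positive checks
use 200 traces of ≤ 30 points and 100 pure-noise PICs of 60 points. These
sizes give stable aggregate statistics (200 true species, 200 decoys) while
keeping a full study run in seconds on one core.

## Known limitations

- Charge-1 assumption; no deconvolution of co-eluting overlapping peaks
  (overlaps are flagged, not resolved).
- Noise estimation from ≤ 30-point traces has small-sample variance (see
  above); `snr_threshold` trades this against sensitivity.
- One run per invocation; no multi-sample alignment or batch comparison.
- The m/z 116.0473 handle also fires on isomeric neutral losses; the
  package reports, it does not identify.
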