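# Methods

## Mass model

All arithmetic is carried out at full double precision from a pinned
atomic-mass table (`src/isopair/data/constants.yaml`; CODATA/AME values to
≥ 8 decimals), so results are bit-stable across installations; m/z values
are rounded to 4 decimals only for display. The propanoyl tag adds the net
composition C₃H₄O (56.026215 Da) per acylated O–H; the heavy tag substitutes
¹³C₃, giving a pair delta of 3·(m(¹³C) − m(¹²C)) = 3.010065 Da. Adduct
shifts (H⁺, Na⁺, NH₄⁺) include the electron mass lost on cation formation
(≈0.549 mDa) — omitting it would bias every neutral mass by ~0.5–1 ppm,
comparable to the matching tolerances. "none" denotes intrinsic cations
(e.g. pyridinium alkaloids), for which the observed m/z *is* the compound
mass. `tagged_mz` and `parent_mz_from_tagged` are exact inverses; charge is
a parameter everywhere but defaults to 1, the charge state implied by a
+3.0101 pair split. Tag and adduct definitions live in the same YAML file
and can be replaced wholesale by a user config, e.g. for a D₃-acetyl tag.

## Pair detection

Within one feature table, every peak is a candidate light twin. For each
searched tag count *n* (default {1}) the expected heavy position is
`mz + n·pair_delta/charge`; a peak within the tolerances completes a hit:

| parameter | default | meaning |
|---|---|---|
| `mz_ppm` | 3 ppm | half-width ppm window around the expected heavy m/z |
| `rt_window` | 0.05 min | half-width co-elution window |
| `intensity_max_rel_diff` | 0.33 | max \|I_L − I_H\| / max(I_L, I_H) |

The ppm error is evaluated against the expected heavy position (the shifted
hypothetical table), signed. The intensity criterion is deliberately
symmetric — "up to 33 % difference" does not name a denominator, and
max(I_L, I_H) avoids treating light and heavy asymmetrically while keeping
the statistic in [0, 1]; with both intensities zero it is defined as 0.
All qualifying pairs are emitted; `deduplicate_hits(strategy="best_ppm")`
optionally keeps one hit per light peak (minimal |ppm|, ties by |ΔRT|, then
smaller heavy m/z). The join sorts by m/z once and window-scans with binary
searches, O((N+H) log N); an all-pairs reference implementation with the
identical contract (`brute_force_pairs`) exists purely as a test oracle and
the suite asserts set-equality of the two on hundreds of randomized tables.

Why the filters work: an untagged compound's natural M+3 satellite sits at
the *same* 3.010 Da spacing (three endogenous ¹³C), so the m/z filter alone
cannot reject it — but its intensity is ~0.5–1.5 % of M+0 even for large
small molecules, two orders below the 33 % cutoff. The intensity filter is
therefore the decoy killer, and the tests include an explicit control
showing an equal-intensity M+3 *would* pass.

## Pre/post comparison

Hit tables from the extract ("pre") and the cell lysate ("post") are
matched on the light peak's m/z and RT at ±4 ppm and ±0.5 min — looser than
the within-run tolerances because calibration and RT drift between
injections exceed within-spectrum error. ppm is computed against the mean
of the two m/z values so matching is order-symmetric. Assignment is
one-to-one greedy in order of increasing |ppm| (ties by |ΔRT|), which makes
the report deterministic and a true partition: matched + pre-only exhausts
the pre hits, matched + post-only the post hits. The enrichment fraction is
|matched| / |pre hits| (0 when there are no pre hits). Only
presence/absence is compared; quantitative fold-change from intensities is
out of scope.

## Synthetic data

`generate_extract_tables(SyntheticSpec(...))` emulates the structure of a
tagged-extract screen; all randomness comes from numpy's PCG64
(`default_rng(seed)`), so tables are pure functions of the spec.

* **Tagged compounds** (default 500): parent m/z uniform on 150–1000 Th,
  RT uniform on 1–48 min (a ~50 min gradient), base intensity log-uniform
  over 10⁴–10⁷. Each emits a light and a heavy peak; light/heavy intensity
  imbalance is lognormal with σ_log = 0.10 around 1:1 (equimolar tagging).
* **Mass error**: per-peak ppm error with sd `mz_jitter_ppm` (default 1,
  typical well-calibrated Orbitrap accuracy), decomposed into a
  compound-shared calibration component (fraction 0.8 of the sd) and an
  independent centroiding component (sd·√(1−0.8²)). Co-eluting isotopologues
  are measured in the same scans, so most of their mass error is common
  mode: the *pair spacing* error (sd ≈ 0.85 ppm at the defaults) is smaller
  than either absolute error, which is exactly why a ±3 ppm pair window is
  usable at 1 ppm instrument accuracy. Pre and post tables draw independent
  errors (separate injections).
* **RT error**: independent per-peak Gaussian, sd 0.005 min (sub-second
  apex reproducibility within a run).
* **Background** (default 5000 pre, 2000 post): untagged features spanning
  the same m/z region, optionally with natural-isotope satellites at
  M+1 ≈ 20–35 %, M+2 ≈ 3–8 %, M+3 ≈ 0.5–1.5 % of M+0, spaced by
  m(¹³C) − m(¹²C). The ranges are qualitative choices mimicking small-
  molecule envelopes below ~1500 m/z, configurable, not measured values.
* **Post table**: a fixed-size subset of round(`binder_fraction`·n)
  compounds (default 8 %) reappears at `post_attenuation` = 0.5 of its
  extract intensity, plus `n_metabolite_only` = 5 pairs present only post
  (metabolized parents) and fresh cell background.

The ground-truth registry maps every emitted tagged peak to its compound,
and `evaluate_detection` scores hits as TP/FP/FN by (light_id, heavy_id,
n_tags) identity.

What the simulator does **not** model: chromatographic peak shapes and
tailing, adduct multiplicity (each compound ionizes once), multiply tagged
species by default, correlated RT drift between runs, intensity-dependent
mass error, and in-source fragments. Passing tests therefore demonstrate
the algorithmic correctness of the joins and arithmetic under realistic
noise magnitudes — not robustness to every pathology of real extracts,
where visual review of hits remains advisable.

## Numerical and design choices

* Tolerances are half-widths ("±") throughout; boundary values pass (≤).
* Hit frames are sorted canonically (light_id, heavy_id, n_tags), so
  results are independent of input row order and reruns are byte-identical.
* CSV parsing coerces numerics and drops invalid rows with a count in the
  table's provenance rather than failing — real exports contain footers and
  blanks. A table with *no* valid rows raises `EmptyTableError` (an
  explicit signal); an empty table passed onward yields empty hit tables,
  not errors.
* The MS-DIAL column map (`Average Mz` / `Average Rt(min)` / `Height`,
  ver. 4.x alignment export) is data, not code: header names drift across
  versions, so any custom map may be passed instead. Peak height is the
  default intensity measure.
* Table sizes in the test suite (≤500 peaks for the all-pairs oracle, 10
  seeds × 21 000 peaks for recovery) keep the whole suite under ~10 s while
  holding the statistical assertions (pooled recall ≥ 0.99, precision
  ≥ 0.95) well away from their thresholds under the stated noise model.

## Known limitations

* Pair detection assumes the heavy twin is resolvable from the light
  compound's natural M+3 satellite; for a tagged compound both are present
  and ~0.01 Da apart at n = 1 — real resolution limits may merge them,
  which the simulator does not model.
* Greedy one-to-one matching is order-deterministic but not globally
  optimal; with dense hit tables an assignment-problem solver could differ.
  At the tolerances used, candidate conflicts are rare.
* Multiply charged species are supported arithmetically but the default
  search assumes z = 1; charge deconvolution is upstream work.
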