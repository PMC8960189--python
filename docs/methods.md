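# Methods

This note documents the models, defaults and numerical choices behind
`nimotif`, and what the synthetic-data tests do and do not demonstrate
about real proteomes.

## Motif model and scanning

The Ni²⁺-hydrolytic motif is a fixed six-position pattern
X₁-[ST]-{CP}-H-{C}-X₂: any residue, Ser/Thr (the cleaved bond precedes
it), anything but Cys/Pro, His (the Ni²⁺ anchor), anything but Cys, any
residue. The fast variant fixes X₁ = Gly. The parser accepts only the
pattern subset these motifs need (single residues, `x`, `[..]`, `{..}`,
dash-separated); repetition counts and anchors are rejected rather than
silently misread.

Ambiguity codes (B, J, O, U, X, Z) are retained in sequences but
satisfy no pattern position by default, including `x`: a residue of
unknown identity cannot be certified to satisfy "not C". The
`ambiguous_as_any` switch restores permissive matching everywhere
except explicit allowed classes. The same codes are excluded from both
numerator and denominator of background composition.

**Overlap merging.** Overlapping windows describe one contiguous
cleavable region and are counted once. The default rule merges
transitively: windows sharing at least one residue chain into a single
hit spanning the first start to the last end, with the hit's X₁/S-T
annotation taken from the first window. An alternative `share_st` mode
merges only windows with an identical S/T position; for fixed-length
patterns this degenerates to no merging (distinct starts never share
the S/T slot) and exists for completeness. Coordinates are reported
1-based inclusive; internal arithmetic is 0-based half-open.

Motif density is merged count × 100 / sequence length (motifs per 100
residues).

## Census statistics

**X₁ enrichment.** Observed X₁ composition is hit-weighted (one count
per merged hit). The enrichment score is log₂(observed/background);
zero means the residue appears at X₁ exactly at its proteome abundance.
A difference score (observed − background) is available via
configuration. Residues never observed get a −∞ sentinel plus an
`absent` flag rather than a fabricated finite value.

**Density CDFs.** Each protein contributes one step of height 1/n at
its density; ties stack. The expected G-motif CDF is the X-motif CDF
with every density scaled by the glycine background fraction f_G: if
X₁ were drawn at background frequency, a fraction f_G of X-motifs would
be G-motifs, so quantiles scale by f_G while step heights are
unchanged. f_G is recomputed from whatever record set is supplied (on
human-like backgrounds it is ≈ 7 %).

**Poisson count model.** Under the assumption that motif occurrences
are uncorrelated, per-protein counts are Poisson and the histogram
should follow n·P(k; λ). λ is the maximum-likelihood mean taken over
the *central portion* of the histogram: the contiguous run of count
values around the modal bin whose bins each hold at least
`min_bin_count` (default 5) observations. Contiguity matters — an
isolated, well-populated tail bin (a block of repeat proteins) would
otherwise enter the fit and inflate λ, masking exactly the deviation
the analysis is meant to expose.

Per-bin 95 % bands treat the observed bin count as Poisson with mean
equal to its expectation and use exact 2.5/97.5 % quantiles (a normal
approximation n_e ± 1.96√n_e is available via `exact_bands=False`).
Discrete quantiles can fall below a fractional expectation in sparse
bins; bands are clamped to always bracket the expectation.

**Outlier flagging.** Ignoring empty bins, the outlier region is the
suffix of occupied bins that all exceed the upper band. It is accepted
only when persistent: at least `persistence` (default 2) occupied bins,
or a total excess over the upper bands of at least `persistence`
proteins. A single bin marginally above its band is therefore never
flagged, while a block of repeat proteins piled far in the tail —
one enormous bin or several adjacent ones — is. The threshold is the
first count of that region; proteins at or above it are reported.
Measured false-flag rate on pure Poisson data is ≈ 0.5 % per run.

## Over-representation testing

Per term, the p-value is the upper-tail hypergeometric probability of
observing ≥ k study hits given K population members of the term, n
study proteins and N population proteins (one-sided Fisher exact test),
followed by Benjamini–Hochberg step-up adjustment across terms. Only
the classic independent per-term test is implemented; graph-aware
decorrelation (elim/weight-style) is out of scope. Isoform collapsing
is a hook taking a user-supplied isoform→canonical mapping; no collapse
rule is guessed.

## Kinetics

The consecutive first-order scheme A → B → C has closed forms

    A(t) = A₀ e^(−k₁t)
    B(t) = A₀ k₁/(k₂−k₁) (e^(−k₁t) − e^(−k₂t))
    C(t) = A₀ − A(t) − B(t)

The product curve is defined by mass conservation rather than an
independent exponential expression, so A + B + C = A₀ holds identically
for all parameter values — including the degenerate branch k₁ ≈ k₂,
where B switches to the limit A₀k t e^(−kt) when the rates differ by
less than 1e−8 relatively. Both branches agree with direct ODE
integration to better than 1e−6.

**Fitting.** All observed species are fitted jointly by weighted
nonlinear least squares (equal weights by default; per-species weights
configurable since instrument precision varies). Rates are optimised
on a log scale, which enforces positivity, from a multi-start grid of
log-spaced rate pairs (default 5×5 over 1e−4…1 min⁻¹); the basin with
the lowest residual is reported and `swap_ambiguous_` records whether a
swapped-rate basin came within 1 % of it — the k₁/k₂ exchange is the
model's intrinsic near-degeneracy when only some species are observed.
A sequential mode (substrate-only exponential first, joint refinement
after) is available. Standard errors are Gauss–Newton
(s²(JᵀJ)⁻¹) and 95 % curve envelopes use the delta method with
numerically differentiated sensitivities.

Time is minutes throughout I/O; condition labels (pH, temperature) are
carried as metadata only — no Arrhenius or pH-rate model is fitted, and
condition comparisons are reported as rate ratios k_a/k_b with
first-order error propagation. The mechanistic additivity of per-site
cleavage rates to the whole-domain decay rate is exposed as a plain sum
with an observed/expected ratio.

The pseudo-first-order product fit y = A₀(1 − e^(−kt)) serves data
where only final products are quantifiable (gel densitometry); it
refuses flat traces.

**Hill titrations.** The titration model is base-10,
A(pH) = A_min + (A_max−A_min)/(1 + 10^(n(pKa−pH))), with all four
parameters free by default (n can be fixed). Initialisation takes the
plateaus from the data extremes and the pKa from the half-signal point;
decreasing titrations fit naturally with A_max < A_min, leaving the pKa
invariant. A fit whose midpoint lands more than one pH unit outside the
sampled range is rejected as "no transition in range".

## Synthetic data

Generators are pure functions of parameters + seed (byte-identical
reruns, single `numpy` Generator per artifact) and always emit ground
truth beside the data.

- **Proteomes**: i.i.d. residues at a human-proteome-like background
  (glycine pinned at 7.07 %, the rest renormalised from standard
  composition averages), lengths log-normal with median ≈ 375 residues;
  Poisson(λ_spike)-distributed motifs per protein (default 0.5) drawn
  uniformly from each position's satisfying residue set and inserted at
  uniform non-overlapping positions; an optional outlier block of
  repeat-protein-like entries with a fixed large motif count. Chance
  motifs arising from the background are not suppressed — truth tables
  carry both planted counts and scanned-truth counts.
- **Time courses**: model values plus i.i.d. Gaussian noise (default
  σ = 0.01), clipped to [0, 1.05]; default 15 points out to ~4
  half-lives of the slower step.
- **Titrations**: Hill curve over pH 3–11.5 in 0.25 steps plus
  Gaussian noise.
- **Annotations**: independent term membership at a base rate (default
  5 %), with one term's study-set membership raised to a stated odds
  ratio.

What passing tests show: the scanner is exactly equivalent to an
independent brute-force oracle; fits recover known parameters at
realistic noise with calibrated intervals; the Poisson stage detects
planted repeat-protein blocks without false-flagging null data. What
they do not show: real proteomes are not i.i.d. — repeats, low
complexity regions and composition biases make real count histograms
overdispersed, which is precisely why the outlier analysis, not the
Poisson fit alone, carries the biological conclusion. Headline
percentages measured on synthetic proteomes depend on λ_spike and the
background and are not estimates of any database release's values.

## Problem sizes

The test suite and the acceptance script use 10,000-protein synthetic
proteomes for calibration checks, 200 replicates for recovery/coverage
simulations, 100 replicates for term-ranking checks and 1,000 random
sequences for oracle equivalence — sizes at which the binomial noise of
the measured percentages is comfortably below the thresholds asserted.

## Known limitations

- Similarity-based redundancy removal is out of scope; deduplication is
  exact-sequence only, with a hook for user-supplied cluster
  representatives.
- The scanner is pure Python; on multi-million-protein inputs it is
  CPU-bound (≈ 1 ms per 450-residue protein for both patterns).
- GO-graph ancestor propagation is off by default and no OBO parsing is
  performed; annotation maps are flat TSVs.
- The k₁/k₂ swap ambiguity cannot be resolved from product-only data;
  use the intermediate trace or the `swap_ambiguous_` flag.
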