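# nimotif

Proteome-wide census of Ni²⁺-hydrolysis-susceptible peptide motifs, with
fitting of the associated hydrolysis kinetics and pH titrations.

Ni²⁺ ions released from alloys and airborne particles can cleave the
peptide bond preceding a serine or threonine inside the six-residue
motif **X₁-[ST]-{CP}-H-{C}-X₂**: the histidine anchors a square-planar
4N Ni²⁺ complex, an N–O acyl shift (rate *k₁*) forms an ester
intermediate, and spontaneous ester hydrolysis (rate *k₂*) releases two
peptide products. The glycine-headed variant **G-[ST]-{CP}-H-{C}-X₂**
("G-motif") is cleaved much faster. Proteins dense in these motifs —
epidermal barrier proteins such as filaggrin above all — are candidate
targets of nickel toxicity and allergy.

`nimotif` lets you run that analysis end to end on any proteome:

- **Motif census** — PROSITE-style pattern scanning with merging of
  overlapping windows, per-protein counts and densities (motifs per
  100 residues), X₁ residue enrichment over the proteome background
  (log₂ observed/background), empirical density CDFs including the
  glycine-corrected expected G-motif CDF, and a Poisson model of
  per-protein counts with exact 95 % bands that flags repeat-protein
  outliers.
- **Functional enrichment** — classic per-term Fisher exact test of
  motif-bearing protein sets with Benjamini–Hochberg adjustment.
- **Kinetics** — the consecutive first-order model
  A(t) = A₀e^(−k₁t), B(t) = A₀k₁/(k₂−k₁)(e^(−k₁t) − e^(−k₂t)),
  C(t) = A₀ − A − B, fitted jointly to substrate / intermediate /
  product time courses; pseudo-first-order product fits with half-lives
  t₁/₂ = ln2/k; condition rate ratios with error propagation; Hill
  fits A(pH) = A_min + (A_max−A_min)/(1+10^(n(pKa−pH))) of
  spectrophotometric titrations yielding the apparent pKa of complex
  formation.
- **Cross-species tables** — motif densities per species and iTOL
  simple-bar annotation export against a Newick tree.
- **Synthetic data** — seeded generators (spiked proteomes with ground
  truth, noisy time courses, titrations, annotations) so every stage is
  testable offline.

The model-fitting components are scikit-learn style estimators
(`MotifScanner`, `PoissonOutlierDetector`, `ConsecutiveKinetics`,
`FirstOrderKinetics`, `HillCurve`) and compose with sklearn tooling.

## Worked example

```python
import nimotif as nm

rec = nm.ProteinRecord("FLG_frag", "filaggrin repeat fragment",
                       "SGGHSAHQAGSSAGHSQASTHEQSGSRSGSAHGQAGSSTGGH")
for h in nm.find_motifs(rec, nm.X_PATTERN):
    print(h.start, h.end, h.x1_residue, h.st_residue)
row = nm.count_motifs(rec)
print(row["n_x_motifs"], row["n_g_motifs"], round(row["density_x"], 2))
```

prints

```
4 9 H S
18 23 A S
29 34 G S
3 1 7.14
```

three merged X-motifs (one of them a G-motif at 29–34, glycine before
the cleaved serine) in a 42-residue fragment, i.e. 7.14 motifs per 100
residues — filaggrin-like density.

Fitting a simulated hydrolysis time course and a titration:

```python
tc, truth = nm.gen_timecourse(k1=0.10, k2=0.05, A0=1.0, sigma=0.01, seed=7)
fit = nm.fit_consecutive(tc)
print(fit.k1_, fit.k2_)          # 0.0992 ± 0.0008, 0.0509 ± 0.0003 1/min

tab, _ = nm.gen_titration(pKa=5.6, n_hill=1.2, sigma=0.02, seed=7)
print(nm.fit_hill(tab).pKa_)     # 5.581 ± 0.015
```

The acyl-shift and ester-hydrolysis rates come back within 1 % of the
simulated truth and the pKa within 0.02 units, with Gauss–Newton
standard errors.

A CLI wraps the pipeline:

```sh
nimotif simulate --n-proteins 1000 --seed 1 --out-dir sim
nimotif census --fasta sim/proteome.fasta --out-dir census_out
nimotif kinetics --timecourse course.csv --titration titration.csv
nimotif species-table --fasta filaggrins.fasta --tree species.nwk
```

`census` writes per-hit and per-protein TSVs, enrichment and CDF
tables, the Poisson report with 95 % bands and outlier list, and a
summary JSON (fraction of proteins with ≥1 X-/G-motif, fitted λ,
outlier thresholds).

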