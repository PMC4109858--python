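# selindel

**How much of a genome is under purifying selection against insertions and
deletions — and how quickly does that functional sequence turn over?**

`selindel` estimates α_selIndel, the fraction of a genome constrained with
respect to indel mutations, from pairwise whole-genome alignments, and fits
a time-homogeneous model of functional-sequence turnover across species
pairs.  It is aimed at comparative genomicists quantifying lineage-specific
constraint that pan-mammalian conservation scores (PhastCons/GERP-style)
cannot see.

## The model

In neutrally evolving sequence, indel events are scattered approximately at
random, so the distance *x* between neighbouring indels (an **inter-gap
segment**, IGS) is geometrically distributed: log-counts of IGS lengths
fall on a straight line with slope ln(1 − θ).  Sequence under selection
against indels interrupts this law — long IGSs are over-represented.  Two
estimators quantify the excess:

* **NIM1** (regression): fit the neutral geometric over medium IGS lengths,
  then sum `x − 2K` over IGSs in excess of the neutral expectation at
  lengths above a threshold *T*, where `K` is the **neutral overhang** —
  the expected spacing from a constrained segment's edge to the nearest
  indel.  Each excess segment is credited with its length minus two
  overhangs: a deliberate lower bound.  Analyses are stratified into
  equally populated regional G+C bins (the X chromosome kept apart) and
  summed.
* **NIM2** (likelihood): maximum likelihood under a mixture in which an IGS
  is neutral-geometric with probability 1 − π, or the sum of a geometric
  constrained core (mean μ_c) and two neutral overhangs with probability π;
  α_selIndel = π·N·μ_c.

Constrained amounts observed between pairs at divergence *d* (substitutions
per neutral site, summed over both branches, measured from ancestral-repeat
alignments under HKY85) decay as

    amount(d) = a · exp(−b·d)

where *a* is the present-day constrained amount and *b* the turnover rate
in events per neutral substitution.  The turnover half-life is
d½ = ln 2 / b, converted to years with a substitution rate of 2.2×10⁻⁹ per
site per year.

The package also provides log-odds alignment rescoring and trimming (to
strip spuriously aligned block ends and internal segments before
estimation) and a two-lineage genome simulator with known constrained-element
truth that validates every estimator.

## Worked example

Simulate a 5 Mb genome pair (5% constrained truth, divergence 0.3), then
estimate constraint:

```python
from selindel import NeutralIndelModel, SimConfig, simulate

blocks, truth = simulate(SimConfig(length=5_000_000, d_total=0.3,
                                   alpha_true=0.05, seed=1))
res = NeutralIndelModel.from_blocks(blocks, n_bins=1).fit(method="nim1", seed=1)
print(f"truth {truth.mutual_bp} bp, estimate {res.alpha_bp:.0f} bp "
      f"({100 * res.alpha_fraction:.2f}% of aligned)")
print(res.summary())
```

prints

```
truth 250316 bp, estimate 228480 bp (4.89% of aligned)
Neutral indel model (NIM1) constraint estimate
====================================================
alpha_selIndel            228479.6 bp  (4.886% of aligned)
95% CI              [209225.1, 247734.1] bp
strata              1 fitted
----------------------------------------------------
  bin     alpha_bp     theta        K      T
    1     228479.6   0.02955     35.4    111
```

The estimate sits just below the simulated truth — the `x − 2K` summation
is a lower bound, and elements shorter than the detection threshold are
missed.  θ ≈ 0.030 matches the simulated indel density (two branches ×
0.15 substitutions/site × 0.1 indels per substitution), and K ≈ 35 bp is
the implied neutral overhang.

Turnover conversions use the fitted decay rate directly:

```python
from selindel import fit_turnover, half_life, divergence_to_years
d_half = half_life(2.48)                      # 0.2795 divergence units
divergence_to_years(d_half) / 1e6             # 127.0 My
```

A command-line interface mirrors the library
(`selindel simulate|trim|alpha|divergence|turnover|pipeline|plot`).

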