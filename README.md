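# tecelong

Kinetics of RNA polymerase elongation through archaeal histone-based
chromatin: a seeded stochastic simulator of ternary elongation complexes
(TECs), a synthetic gel-densitometry layer, marker-calibrated lane
quantification into seven transcript-length bins, and the kinetic
statistics built on those bins.

## The problem

In reconstituted archaeal transcription assays, TECs are stalled with a
58-nt nascent RNA by nucleotide deprivation, the DNA downstream is coated
with histone dimers (wild-type or variant), and elongation is restarted so
that RNA synthesis to the +231 template end can be followed on denaturing
gels over a 15–240 s time course. Because the polymerase occludes ~20 bp
ahead of the RNA 3' end and each histone dimer protects ~30 bp, the TEC
first collides with chromatin at transcript position ~+70 and again every
30 nt (~+100, +130, +160, +190) — but only the first collision produces a
substantial pause. Quantifying those gels means: calibrating pixel
position against size standards by linear regression, parsing each lane
into seven RNA-length bins, and reducing the binned time courses to a few
kinetic numbers.

This package implements that quantification pipeline and drives it with a
kinetic simulator, so every stage is testable against exact ground truth
without any experimental data.

## The model and the statistics

The simulator is a pure birth chain over transcript lengths
`L ∈ {58, …, 231}`: escape from the stall occurs at rate `k_release`,
every other single-nucleotide addition at rate `k_step`, divided by a
barrier factor `β ≥ 1` at barrier-encounter positions; +231 is absorbing.
TFS (the cleavage-stimulatory factor) multiplies `k_release` and divides
`β`. An exact transient solver (`p(t) = p(0)·e^{Qt}`) serves as the
oracle for the sampler.

From seven-bin fractions `f_b` with bin midpoints `m_b` the package
computes, per the field's conventions:

- mean transcript length `L̄(t) = Σ_b f_b·m_b`;
- average elongation rate `r = mean_t[(L̄(t) − 58)/t]` (nt/s), and rates
  relative to the histone-free template;
- pause kinetics at +58 from the two-point exponential
  `C2 = C1·e^{−k(t2−t1)}` with `t1 = 15 s`, `t2 = 240 s`, giving
  `t_1/2 = ln 2 / k`, and half-lives relative to WT without TFS
  (reference entry ≡ 1.00);
- full-length fractions and replicate mean ± SE summaries.

## Worked example

`examples/04_study_kinetics.py` simulates the full study design — 10
chromatin landscapes × (4 replicates −TFS, 3 +TFS) × 5 timepoints — and
prints the kinetics table. Abridged output:

```
condition  tfs  rate_nt_s  relative_rate  full_length_fraction  t_half_s  relative_t_half
HTkA-free    0      1.319          1.000                 0.980    40.183            0.291
       WT    0      0.465          0.353                 0.675   137.953            1.000
       WT    1      0.760          0.576                 0.871    76.010            0.551
E19K/G52K    0      0.197          0.149                 0.289    62.135            0.450
```

`relative_rate` ranks the landscapes by how strongly their first barrier
slows elongation (histone-free fastest, the tight-binding double mutant
slowest); `relative_t_half` is the +58 pause half-life over the WT −TFS
value, which is 1.000 exactly by construction; TFS shortens every
half-life because it boosts release from the stall. The other examples
cover template geometry (`01`), single time courses against the exact
oracle (`02`), and the gel synthesize→quantify round trip (`03`).

A thin CLI wraps the same functions:

```
tecelong simulate --seed 7 --out bins.csv
tecelong synthesize-gel --variant WT --seed 3 --out gel/
tecelong quantify gel/ --out bins.csv --calibration-out cal.json
tecelong stats bins.csv --out kinetics.csv
tecelong run-all --seed 7 --out-dir study/
```

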