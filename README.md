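# panrep

Repertoire analysis for **in-vivo phage-display biopanning of VHH (nanobody)
libraries**, with a ground-truth biopanning simulator.

In an in-vivo selection experiment, a naive VHH phage library is injected
into tumor-bearing animals; phage are recovered from sorted immune-cell
subtypes (CD45 bulk, CD11b, CD11c, CD8, CD4CD25⁻, CD4CD25⁺) over successive
biopanning rounds (BP0–BP4), each round re-seeded from the amplified bulk
pool.  Paired 300 nt amplicon reads are sequenced per sample.  `panrep`
answers the questions such an experiment poses:

* **Reconstruction** — overlap-merge read pairs, strip constant flanks, and
  annotate full-length VHHs (FR1–CDR1–FR2–CDR2–FR3–CDR3–FR4) against a
  scaffold consensus, validating the four structural anchors (FR1 Cys,
  FR2 Trp, FR3 Cys, FR4 [WF]-G-x-G); partial reconstructions are removed.
* **Clonotyping & diversity** — clonotype tables (full amino-acid, CDR3
  amino-acid, or CDR3 nucleotide keys), top/rare clone proportions, percent
  unique VHHs, Shannon *H*, Simpson index, Hill-number true diversity
  *D_q = (Σ pᵢ^q)^{1/(1−q)}* (with *D₁ = e^H*), analytic hypergeometric
  rarefaction and Chao1-based extrapolation.
* **Enrichment & selectivity** — clone trajectories across rounds, a
  late-over-early screen (pseudocounted BP3+BP4 mass over BP1+BP2 mass),
  per-clone selectivity shares across the five sorted subtypes (rows sum
  to 1), venn-style overlaps, and recovery of Sanger-picked clones in the
  NGS tables at the CDR3 level.
* **Simulation** — a seeded generator producing libraries with realistic
  CDR3 length profiles (median 18 aa, range 1–36), multi-round
  affinity-driven multinomial selection with lognormal amplification noise,
  and paired-FASTQ read emission with substitution errors, plus full truth
  tables, so every stage above is testable against known ground truth.

## Worked example

Run the full simulated experiment end-to-end (five subtypes, four rounds,
three replicate mice) and inspect the result:

```python
from panrep import run_pipeline
from panrep.pipeline import default_scenario_config

result = run_pipeline(default_scenario_config(seed=1), outdir="panrep_out")
report = result.report

print(report.samples["BP1_CD45_rep0"])
print({r: round(v["d1"]) for r, v in report.diversity["CD45"].items()})
print(report.enrichment["CD11c"])
print(report.selectivity["assigned_counts"])
```

prints (exactly reproducible at this seed):

```
{'pairs': 4500, 'merged': 4500, 'length_ok': 4500, 'quality_ok': 4500, 'extracted': 4500, 'complete': 4495}
{'0': 599, '1': 603, '2': 254, '3': 29, '4': 14}
{'n_clones': 2067, 'n_pass': 30}
{'CD11b': 10, 'CD11c': 9, 'CD4CD25neg': 10, 'CD4CD25pos': 9, 'CD8': 10}
```

Reading this output: all 4,500
read pairs of the BP1 bulk sample merge and annotate (five reads carry a
substitution that breaks an anchor and are dropped as partial); the bulk
pool's effective number of clonotypes (*D₁*) collapses from ~600 in
BP0/BP1 to ~14 by BP4; the CD11c stream's late-over-early screen passes 30
clones — binders of *all* subtypes rise in the shared bulk pool, so each
stream's screen also surfaces the other subtypes' binders, and it is the
selectivity matrix that resolves the target cell type: 48 of the 50 planted
binders are recovered and assigned (10/10 CD11b, 9/10 CD11c, …; the two
missing binders were drift-extinct before ever being sequenced).  The same
analysis is scriptable from the shell via the
`panrep` command (`simulate`, `merge`, `annotate`, `tabulate`, `diversity`,
`clonality`, `track`, `enrich`, `select`, `overlap`, `sanger-compare`,
`run`).

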