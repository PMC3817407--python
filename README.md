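# ecfkit

Tools for designing orthogonal gene-regulatory parts from extracytoplasmic
function (ECF) sigma factors: bipartite promoter models and genome mining,
sigma x promoter crosstalk analysis and orthogonal-subset selection, and
sigma / anti-sigma sequestration switches.

## The problem

ECF sigma factors are the smallest alternative sigma subunits of bacterial
RNA polymerase. Each has two DNA-binding domains — domain 4 reads the
promoter's −35 element, domain 2 the −10 element — separated by a variable
spacer. Because different ECF subgroups read different −35/−10 motif
combinations, they are a natural source of *orthogonal* regulators for
synthetic circuits: a sigma should fire its own promoter strongly and
everyone else's not at all, and its cognate anti-sigma should silence only
it. `ecfkit` implements the computational side of building such a part
collection:

- **Promoter models** (`motif_model`): a model is
  `PWM(−35) + spacer penalty + PWM(−10)` in log2-odds units. The spacer
  penalty is `log2 p̂(L)/p̂(L_mode)` from a pseudocount-smoothed spacer
  histogram (0 at the modal spacing). `scan_promoter` returns the
  maximum-scoring placement over all (−35 offset, spacer) pairs, and
  `discover_two_block` learns such gapped two-block motifs de novo from
  unaligned upstream regions with a collapsed Gibbs sampler (one site per
  sequence, variable gap).
- **Promoter mining and design** (`promoter_design`): operon-aware
  upstream-region extraction from annotated genomes, scoring of candidates
  against all subgroup models, exclusion of candidates resembling host
  sigma70/FecI promoters, A/T-rich UP-element replacement of −60..−36, and
  the combinatorics of chimeric sigmas (distinct −35 classes x distinct
  −10 classes).
- **Crosstalk analysis** (`crosstalk_analysis`): fold induction and
  repression, strict >5-fold / >2-fold activity calls, per-pair off-target
  load (baseline-subtracted folds over a pair's row and column), greedy
  selection of the k most orthogonal pairs, and Spearman comparison of
  predicted scores against measured folds. Growth-rate and percent-of-WT
  toxicity helpers round out the screen bookkeeping.
- **Switches** (`switch_titration`): an anti-sigma sequesters its sigma by
  1:1 equilibrium binding (free sigma solves
  `S² + (A + K_d − S_tot)S − K_d S_tot = 0`); the output promoter responds
  hyperbolically to free sigma. Molecular titration makes the switch
  threshold-gated: raising anti-sigma lowers the OFF state, shifts the
  threshold, and raises the apparent Hill coefficient, which `fit_hill`
  (log-space least squares, multi-start) and `tuning_curve` quantify.
- **Co-occurrence** (`cooccurrence`): do non-crosstalking sigmas
  co-occur with more partners across genomes? A two-sided label-permutation
  test on mean partner counts.
- **Synthetic data** (`synthetic_data`) generates every input with seeded
  reproducibility; `reference` packages a reconstructed 86-sigma /
  62-anti-sigma / 29-promoter library with the published screen arithmetic.

## Worked example

```python
from ecfkit.synthetic_data import MotifSpec, gen_subgroup_promoters
from ecfkit.motif_model import discover_two_block, scan_promoter
from ecfkit.switch_titration import demo_tuning_config, tuning_curve

spec = MotifSpec(consensus35="GGAACTT", consensus10="GTCTGA",
                 per_position_mutation_rate=0.1)
promoters = gen_subgroup_promoters(spec, n=30, seed=7)
model = discover_two_block([p.sequence for p in promoters], w35=7, w10=6,
                           spacer_range=(13, 18), seed=1)
print("discovered:", model.pwm35.consensus, "/ spacer",
      model.spacer.modal_length, "/", model.pwm10.consensus)
hit = scan_promoter(model, promoters[0].sequence)
print(f"best placement: -35 at {hit.start35}, spacer {hit.spacer_length}, "
      f"total {hit.total:.1f} bits")

params, anti_levels, inputs = demo_tuning_config()
print(tuning_curve(params, anti_levels, inputs).summary())
```

prints

```
discovered: GGAACTT / spacer 16 / GTCTGA
best placement: -35 at 24, spacer 16, total 20.6 bits
anti_level	basal	threshold_k	n
0	401	3	1
10	2.639	13.68	8.31
30	2.049	35.7	10.6
100	1.582	100.3	12
300	1.398	288.2	11.7
800	1.327	785.1	12
basal fold-drop 302; threshold shift 262x
```

The Gibbs sampler has recovered the planted −35 (`GGAACTT`) and −10
(`GTCTGA`) consensi and the 16 nt modal spacer from 30 mutated promoter
windows; the scanned promoter places the model at 20.6 bits over
background. The tuning table shows the sequestration phenotype: as the
anti-sigma level rises, the OFF-state output (`basal`) drops ~300-fold,
the induction threshold (`threshold_k`) tunes across more than two orders
of magnitude, and the apparent cooperativity (`n`) climbs from 1 toward
the fit bound.

A command-line interface mirrors the pipeline stages:

```
ecf synth promoters --n 30 --seed 7 --out proms.fa
ecf motif discover --fasta proms.fa --out model.meme
ecf motif scan --model model.meme --fasta proms.fa --out hits.tsv
ecf crosstalk select --matrix folds.tsv --k 20
ecf switch tune
ecf cooccur --matrix presence.tsv --group-a sg00,sg01 --group-b sg02,sg03
```

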