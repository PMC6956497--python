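# seedscan

Accessibility-based RNA-RNA interaction prediction with a full suite of
seed and interaction constraints, plus a target-screen recovery benchmark
for bacterial sRNAs.

Small regulatory RNAs (sRNAs) repress or activate bacterial mRNAs by
base-pairing near the start codon.  In-silico target screens score an
sRNA against every start-codon window in a genome and rank targets by the
stability of the best predicted interaction; their accuracy hinges on two
ingredients - requiring a *seed* (a short, perfectly stacked initial
helix) and charging each interaction for the *accessibility* of its
binding sites.  `seedscan` implements both exactly and makes every
individual constraint switchable, so their impact on a screen can be
measured one at a time.

## Model

An interaction `I` with sites `i..j` on RNA 1 and `k..l` on RNA 2 is
scored by its overall free energy

    E(I) = Eh(I) + ED1(i..j) + ED2(k..l)        [kcal/mol]

- `Eh`: nearest-neighbor hybridization energy of the inter-molecular
  duplex (stacking, interior loops/bulges, initiation, AU/GU end
  penalties), over a compact, pluggable parameter set;
- `ED = -RT ln Pu(site)`: the penalty for freeing each site of
  intra-molecular structure, with `Pu` the exact Boltzmann probability
  that the site is unpaired, from a McCaskill-style inside/outside
  partition function over the same energy model.

`predict` returns the interaction minimizing `E` subject to: a contained
canonical seed (`seedBP` consecutive pairs; optionally GU-free, energy-
bounded via `seedMaxE`/`seedMaxEhybrid`, accessibility-bounded via
`seedMinPu`), maximal interaction length per RNA (`intLenMax`), maximal
loop size (`maxLoop`), an overall energy ceiling (`intMaxE`, default 0),
and minimal site accessibility (`intMinPu`).  `predict_bruteforce`
re-solves the same problem by exhaustive enumeration and serves as the
correctness oracle.  Two presets bundle the constraint choices: `default`
(7-bp seeds, GU allowed, length <= 150, loops <= 16) and `recommended`
(GU-free seeds, seed/site `Pu >= 0.001`, length <= 60, loops <= 8).

See `docs/methods.md` for the full model, algorithms and limitations.

## Worked example

Score an sRNA against an mRNA start-codon window with the recommended
constraint set:

```bash
seedscan predict -q srna.fa -t target.fa --preset recommended -o out.csv
```

`out.csv` starts with a provenance header (tool version, resolved
configuration, input checksums), then one row per reported interaction:

```
id1,start1,end1,id2,start2,end2,hybridDP,E,Eh,ED1,ED2,seedStart1,seedEnd1,seedStart2,seedEnd2
sgrS_like,11,21,ptsG_like,48,58,(((((((((((&))))))))))),-19.3892,-20.2,0.0342,0.7766,11,17,52,58
```

Read: the most stable qualifying interaction pairs sRNA positions 11-21
with target positions 48-58 as a contiguous 11-pair duplex (`hybridDP`
writes both sites 5'->3'; the t-th `(` pairs with the t-th `)` from the
right).  The duplex alone contributes Eh = -20.2 kcal/mol; opening the
sRNA site costs ED1 = 0.03 (essentially unstructured) and the target
site ED2 = 0.78, for an overall E = -19.39 kcal/mol.  The GU-free 7-bp
seed sits at sRNA 11-17 / target 52-58.  All coordinates are 1-based
inclusive.

Other subcommands: `seedscan acc` precomputes accessibility profiles
(`<id>.pu.tsv`, reusable via `--acc-in`), `seedscan fixture` generates a
deterministic synthetic screen (sRNAs, toy genomes + GFF3, planted
interaction sites, verified-pair table), and `seedscan bench` runs the
screen end to end: it extracts start-codon windows (-200..+100) from
genome + annotation, ranks every target per sRNA, counts verified pairs
among the top-100 predictions, and compares configurations by recovery
and relative runtime.

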