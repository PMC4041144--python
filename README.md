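# phyloindel

Comparative analysis of structural (indel) and molecular (dN/dS) evolution
in a protein-coding exon against sperm-competition phenotypes across
closely related species.

## The problem

In promiscuous mating systems the ejaculates of rival males compete to
fertilize ova. The intensity of this sperm competition is well proxied by
**relative testes mass** (RTM): observed combined testes mass divided by
the mass predicted from the allometric regression `testes = a * body^b`.
Reproductive proteins often evolve fast under this pressure — both by amino
acid replacement (measurable as ω = dN/dS, the ratio of nonsynonymous to
synonymous substitution rates) and by in-frame insertions and deletions
(indels) that change protein length. The CatSper1 calcium-channel subunit,
whose histidine-rich intracellular N-terminus is length-variable across
rodents and matters for sperm motility, is the motivating case: does sperm
competition select on the length of this domain, and does length predict
sperm swimming velocity?

`phyloindel` implements the complete analysis chain needed to ask that
question of any aligned coding exon, a phenotype table and a species tree:

1. **io_formats** — gapped FASTA alignments, per-species consensus from
   ≥3 individuals (with substitution/indel polymorphism reports), rooted
   newick trees with outgroup handling, validated phenotype CSVs.
2. **indel_coding** — distinct gap spans coded as binary characters
   (simple indel coding; nested spans are `?`), reading-frame check (all
   indels must be 3n nt), per-species ungapped lengths.
3. **indel_events** — Fitch/Sankoff parsimony mapping of each gap character
   onto the species tree; equally parsimonious placements resolved toward
   the deepest single origin; outgroup polarization into insertions vs
   deletions; homoplasy flags; event summary with hard identity checks.
4. **codon_evolution** — Goldman–Yang 61-state codon model: M0 fit (joint
   ML over κ, ω and branch lengths; its branch lengths feed the PGLS),
   site-class mixtures M1a/M2a and M7/M8/M8a with likelihood-ratio tests,
   naive empirical-Bayes identification of positively selected sites,
   counting (Nei–Gojobori) branch rates and root-to-tip **lineage ω**
   (ΣdN/ΣdS along each root-to-tip path).
5. **residue_stats** — histidine counts/proportions, ancestral
   reconstruction of content shifts, overlap of selected sites with
   histidine positions.
6. **comparative_stats** — RTM, PCA of the seven CASA velocity descriptors
   (VCL, VSL, VAP, LIN, STR, ALH, BCF; PC1 = overall sperm velocity), and
   phylogenetic generalized least squares with Pagel's λ estimated by
   profile ML on [0, 1], λ-boundary LR tests, sequential (Type I) sums of
   squares, Fisher-z effect sizes `atanh(sqrt(F/(F+df)))` with 95% limits
   `± 1.96/sqrt(n−3)`, and outlier diagnostics.
7. **synthetic_data** — a fully book-kept generator (tree, codon sequences
   with in-frame deletion-biased indels, individuals, phenotypes with
   programmed effect sizes) so the whole pipeline is testable end to end
   without any downloads.

## Worked example

```python
from phyloindel import (
    SimulationConfig, simulate_study, species_consensus_alignment,
    find_gap_blocks, code_indels, map_all_events, summarize_events,
    build_codon_alignment, m0_fit, branch_rates_counting, lineage_omegas,
    ungapped_lengths, run_comparative_suite,
)
from phyloindel.residue_stats import histidine_table

study = simulate_study(SimulationConfig(), seed=1)
aln, _ = species_consensus_alignment(study["alignment"])
tree = study["tree"]

matrix = code_indels(find_gap_blocks(aln), aln)
events, _ = map_all_events(matrix, tree)
s = summarize_events(events, tree)
print(f"indel events: {s.total_events} "
      f"({s.deletions} deletions, {s.insertions} insertions)")

caln = build_codon_alignment(aln)
m0 = m0_fit(caln, tree)
print(f"M0: lnL={m0.lnL:.2f} kappa={m0.kappa:.2f} "
      f"omega={m0.params['omega']:.3f}")

rates = branch_rates_counting(caln, tree)
omegas = lineage_omegas(rates, tree)
suite = run_comparative_suite(
    ungapped_lengths(aln).data, omegas,
    histidine_table({t: caln.protein(t) for t in tree.ingroup_tip_labels()}),
    study["phenotypes"], tree, config={"rtm_a": 0.031, "rtm_b": 0.77},
)
row = suite["table2"].query("dependent=='length' and predictor=='RTM'").iloc[0]
print(f"length ~ RTM: slope={row['slope']:.2f} F={row['F']:.2f} "
      f"P={row['P']:.4f} lambda={row['lambda']:.2f}")
```

prints

```
indel events: 35 (25 deletions, 10 insertions)
M0: lnL=-4207.10 kappa=1.99 omega=0.407
length ~ RTM: slope=-7.89 F=39.43 P=0.0000 lambda=0.43
```

The simulated study programs a negative coupling between sperm-competition
level and exon length, so the PGLS finds a strong negative length–RTM slope
(here −7.9 amino acids per RTM unit), while ω itself — simulated without
any RTM dependence — shows no association. Deletions outnumber insertions
by the configured 60:40 bias, and every indel is a multiple of 3 nt so the
reading frame is intact.

The same stages are available from the shell:

```bash
phyloindel simulate --seed 1 --out study/
phyloindel map-events --alignment study/alignment.fasta \
    --tree study/tree.nwk --outgroup Outgroup
phyloindel run-all --config run.yaml
```

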