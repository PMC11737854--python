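# tcrhla

Discovery of HLA-associated public T-cell receptor (TCR) clonotypes from
repertoires of HLA-typed donors, and computational HLA typing of donors from
their repertoires alone.

## Who this is for

Immunologists and computational biologists with bulk TCR repertoire data
(alpha and/or beta chain CDR3 amino-acid sequences with V-gene calls) who
want to (i) find public clonotypes whose presence across donors tracks a
particular HLA allele, (ii) predict the HLA type of untyped donors from
repertoire data, and (iii) mine new TCR–HLA associations from large untyped
cohorts by iterative, semi-supervised typing.

## The method

**Association discovery.** A clonotype is the triple (chain, CDR3
amino-acid sequence, V-gene family). For every *public* clonotype — one
seen in at least 3 donors — and every HLA allele at 4-digit resolution
(e.g. `A*02:01`), donors are cross-tabulated into a 2×2 table (clonotype
present/absent × allele positive/negative) and tested with Fisher's
two-tailed exact test (point-probability rule, exact integer arithmetic).
The Benjamini–Hochberg step-up procedure controls the false discovery rate
across all tests of a run at 1% by default. Alpha-chain clonotypes are only
tabulated over donors whose alpha chain was sequenced.

**Per-allele classifier.** For allele *a*, the probability that a donor is
positive is modelled as

```
p_a = 1 / (1 + exp(−Σ_i w_ai x_i − v_a y − b_a))
```

where `x_i ∈ {0,1}` indicates presence of the *i*-th allele-associated
clonotype in the donor's repertoire, `y ∈ {0,1}` indicates whether the
donor's alpha chain was sequenced, and `b_a` is an optional intercept.
Weights are fitted by L1-penalized maximum likelihood on a 70% training
split; the penalty strength is selected from a geometric grid by
cross-entropy on the held-out 30%. Variants: *fuzzy* feature matching (a
feature counts as present if a repertoire clonotype of the same chain, V
family and CDR3 length is within Hamming distance 1), an L2 penalty, and a
weight-free classifier that simply counts feature matches.

**Iterative typing.** Untyped donors are processed in random subgroups of
100: each subgroup is typed with the current model, appended to the cohort
with its labels frozen, associations are re-discovered with the number of
retained associations budgeted proportionally to the donor count (ratio
fixed at its initial-cohort value, replacing the FDR threshold), and the
classifier is refitted.

**Feature analyses.** CDR3-length profiles and V-family usage of associated
clonotypes vs background, per-V-family Mann–Whitney U comparisons of
whole-repertoire V usage between donor groups, and Hamming-1 similarity
networks (edges join clonotypes of the same chain, V family and CDR3 length
differing by at most one amino acid) with optional epitope annotation by
exact (CDR3, V family) lookup in a user-supplied reference table.

Because real HLA-typed repertoire cohorts are large and access-restricted,
the package ships a synthetic cohort generator (`tcrhla.simulate`) that
plants configurable TCR–HLA associations, so every stage is testable end to
end without external data.

## Worked example

```python
from tcrhla import HlaAllele, discover, fit
from tcrhla.simulate import (PlantedAssociation, SimulationConfig,
                             simulate_cohort, split_cohort)
from tcrhla.evaluation import roc_auc

a0201 = HlaAllele.parse("A*02:01")
cfg = SimulationConfig(
    n_donors=500,
    allele_panel=[(a0201, 0.3)],            # population frequency 30%
    n_background_clonotypes=500,            # HLA-agnostic public clonotypes
    background_sharing=0.1,
    planted_associations=[PlantedAssociation(a0201, 20, p_pos=0.6, p_neg=0.05)],
    seed=0,
)
cohort, truth = simulate_cohort(cfg)

records = discover(cohort, q=0.01, min_publicness=3)
print(len(records), "significant associations")

train, test = split_cohort(cohort, [350, 150], seed=0)
model = fit(train, a0201, associations=records, split_seed=0)
scores = [model.predict_donor(d) for d in test]
labels = [int(d.has_allele(a0201)) for d in test]
print("held-out AUC:", round(roc_auc(scores, labels)[1], 3))
```

Output:

```
20 significant associations
held-out AUC: 1.0
```

The 20 discoveries are exactly the 20 planted clonotypes (none of the 500
background clonotypes slips through at the 1% FDR level), and the
classifier built on them separates carriers from non-carriers perfectly on
the held-out 150 donors.

The same workflows are available from the shell via the `tcrhla` command
(`simulate`, `discover`, `train`, `predict`, `iterate`, `network`,
`evaluate`); every run writes a reproducibility manifest with the seed and
options used.

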