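# counselnet

Leaky noisy-OR Bayesian networks for genetic counseling in dogs.

Many canine genetic disorders — degenerative myelopathy (DM) and its
associated *SOD1* mutation being the motivating example — are recessive
and incompletely penetrant: a dog homozygous for the deleterious allele
(`BB`) may never show clinical signs, and non-genetic factors (diet,
exercise regimen, age) modulate whether signs appear. A veterinarian
advising a breeder therefore needs to answer two questions
quantitatively: *what is the risk that a test-positive animal develops
clinical signs?* and *what is the risk that an untested animal, or a
planned litter, carries the mutant allele, given what is known about its
relatives?* `counselnet` answers both with a small, fully transparent
discrete Bayesian network, and scores mating alternatives by expected
utility.

## Model

For each individual, the probability of clinical signs is a **leaky
noisy-OR** gate over four binary causes — the genetic cause
X₁ (active when the genotype is `BB` under the default recessive model)
and three non-genetic risk factors X₂…X₄ (diet, exercise, age):

```
P(signs | X_p) = 1 − (1 − p₀) · ∏_{i ∈ X_p} (1 − pᵢ)
```

where `X_p` is the set of active causes, `pᵢ` the link probability of
cause i (the probability that the cause alone produces signs) and `p₀`
the leak — the background probability of signs when every modeled cause
is absent. Uncertainty about the leak and link probabilities is carried
by Beta priors (conjugate for probabilities), elicited from a mean and
either a standard deviation or a concentration ν = α + β.

Genotype nodes follow the pedigree: founders carry a prior (uniform over
`AA/AB/BB`, Hardy–Weinberg at allele frequency *q*, or a fixed state);
an offspring's genotype CPT is Mendelian transmission from its sire and
dam. Optional test nodes attach to genotypes with a
sensitivity/specificity CPT. Inference is exact — variable elimination,
cross-checked against full-joint enumeration — and runs forward (risk of
signs) or backward (carrier probabilities from observed relatives).
Decision support attaches utilities `(u_AA, u_AB, u_BB)` to the
offspring genotype and ranks mating alternatives by expected utility.

## Worked example

```python
import counselnet as cn
from counselnet.inference import posterior

# sire, dam, offspring; uniform founder genotype priors;
# gate at the prior means: leak 1%, non-genetic links 10%, genetic link 90%
net = cn.build_trio(cn.table1_groups()[5])

# Backward: the offspring was genotyped homozygous mutant.
rep = posterior(net, "G_sire", {"G_offspring": "BB"})
print({s: round(p, 4) for s, p in zip(rep.states, rep.probabilities)})
```

prints

```
{'AA': 0.0, 'AB': 0.3333, 'BB': 0.6667}
```

— a `BB` pup forces each parent to carry at least one `B`: one third of
the compatible, equally weighted parental states are `AB` and two thirds
`BB`. Forward, in the deterministic limit (leak 0, genetic link 1 — a
`BB` dog always shows signs, others with no active factor never do):

```python
det = cn.build_trio(gate=cn.deterministic_limit_gate(0.1))
ev = {"P_sire": "healthy", "P_dam": "healthy",
      "D_sire": "F", "E_sire": "F", "A_sire": "F",
      "D_dam": "F", "E_dam": "F", "A_dam": "F"}
print(posterior(det, "G_offspring", ev).probabilities)
# (0.5625, 0.375, 0.0625)
eu = cn.expected_utility(det, ev, cn.UtilitySpec(100, 100, 0))
print(eu)  # 93.75
```

Two phenotypically healthy, untested parents leave a 6.25% chance of a
`BB` pup, so valuing any non-affected pup at 100 this mating scores
93.75 against 100 for mating two tested `AA` dogs.

The same computations are available from the shell:

```bash
counselnet counsel --scenario scenario.yaml      # JSON posterior report
counselnet table --group 5 --draws 10000 --seed 1  # risk table, % mean (sd)
counselnet utility --scenario mating.yaml --utilities 100,100,0
counselnet scenarios run                         # reproduction report
```

`counselnet scenarios run` executes every packaged scenario and prints a
reproduction table; published figures whose generating parameterization
is undocumented are listed explicitly as "not reproduced — see notes".

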