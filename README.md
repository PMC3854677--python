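# ddiblocks

Unsupervised prediction of drug–drug interaction types from the network of
previously reported interactions — no pharmacological, chemical or target
information required.

## The problem and the method

Interactions between drugs (adverse interactions in a database, or
synergistic / additive / antagonistic / suppressing effects in a combination
screen) are largely determined by which cellular functions the drugs target.
In network terms: drugs can be partitioned into groups such that the type of
interaction between two drugs depends only on their groups.  That is a
*stochastic block model* with typed edges.

`ddiblocks` estimates the probability that a pair (i, j) interacts with type
k by **Bayesian model averaging** over all block models.  For a partition P
of the drugs, let n^k_{αβ} count the observed interactions of type k between
groups α and β, and n_{αβ} = Σ_k n^k_{αβ}.  Integrating the group-pair type
probabilities over a uniform prior on the K-simplex gives each partition the
weight exp(−H(P)) with

    H(P) = − Σ_{α≤β} ln [ (K−1)! · Π_k n^k_{αβ}! / (n_{αβ} + K − 1)! ]

and the posterior type probability of a pair becomes the average of the
Laplace-smoothed rate (n^k_{σ_i σ_j} + 1)/(n_{σ_i σ_j} + K) over partitions
weighted by exp(−H).  The partition sum is estimated by Metropolis sampling:
move a random drug to a random other group, accept with probability
min(1, e^{H−H'}); many short independent chains (default 50 × 200 thinned
samples) are pooled.  The approach is unsupervised and parameter-free.

The package also implements the comparison methods — the global-rate
baseline, the neighbor-similarity predictor, and the Prism II
monochromaticity clustering — plus the full evaluation protocol
(sub-sampling validation with exact and ±1-level metrics, novel/spurious
interaction detection between database snapshots with AUROC and
sensitivity/specificity, and the iterative guided-discovery simulation), and
planted-partition generators so every claim is testable against known ground
truth.

## Worked example

```python
import numpy as np
from ddiblocks import (
    PlantedModel, SamplerConfig, TypeAlphabet, generate_planted_network,
    link_type_posterior, monochromatic_theta, run_sampler,
)

alphabet = TypeAlphabet(("synergistic", "additive", "antagonistic"), ordered=True)
theta = monochromatic_theta(n_groups=3, n_types=3, dominant_prob=0.9)
planted = generate_planted_network(
    PlantedModel((20, 20, 20), alphabet, theta, observed_fraction=0.5, seed=100)
)

samples = run_sampler(
    planted.observed, SamplerConfig(n_chains=5, samples_per_chain=100, seed=0)
)
pair = next(p for p in planted.truth.all_pairs() if not planted.observed.has(*p))
probs = link_type_posterior(samples, pair)
truth = planted.truth.get(*pair)
print(pair, np.round(probs, 3), "truth:", alphabet.labels[truth])
```

Output:

```
('D000', 'D001') [0.823 0.092 0.085] truth: synergistic
```

The two drugs sit in the same planted group, whose within-group interactions
are synergistic with probability 0.9; the posterior concentrates on the
correct type at almost exactly the planted rate.  Across all held-out pairs
of this network the block-model average classifies ~90% exactly, against
~33% for the global-rate baseline.

The same machinery runs from the shell:

```bash
ddiblocks simulate --style binary --n-drugs 100 --p-in 0.7 --p-out 0.03 \
    --seed 1 --out net.tsv
ddiblocks predict --network net.tsv --alphabet no-interaction,interaction \
    --unordered --method sbm --chains 10 --samples 100 --seed 1 --out scores.tsv
```

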