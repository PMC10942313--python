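"""Compare the two position-selection modes of the composite mutation
operator: random Bernoulli selection versus ranking positions by how
native-like their current residue is and redesigning the worst ones.

On a conflict-free toy problem both selectors eventually recover the
consensus sequence; the ranked selector concentrates mutations on the
positions that are still wrong and gets there in fewer generations.
"""

import numpy as np

from modesign.moea import RunConfig
from modesign.runner import run_design
from modesign.synthetic import make_toy_problem

toy = make_toy_problem(conflict_fraction=0.0, seed=100)
consensus = toy.consensus_sequence()
print(f"consensus (both states' modal sequence): {consensus}")


def iterations_to_threshold(selector_kind: str, seed: int, threshold=0.9) -> int:
    config = RunConfig(seed=seed, iterations=50, mutation_rate=0.3,
                       selector_kind=selector_kind)
    history = run_design(toy.problem, config, toy.objective_specs(),
                         ranker=toy.ranker())
    for rec in history.records:
        mean_rec = np.mean([
            sum(a == b for a, b in zip(c.designed_residues, consensus))
            / len(consensus)
            for c in rec.population.members])
        if mean_rec >= threshold:
            return rec.population.iteration
    return -1


print("\niterations until mean consensus recovery reaches 0.9:")
print(f"{'seed':>6} {'ranked':>8} {'random':>8}")
for seed in range(5):
    ranked = iterations_to_threshold("ranked", seed)
    random_ = iterations_to_threshold("random", seed)
    print(f"{seed:>6} {ranked:>8} {random_:>8}")
print("\nSmaller is faster; ranking positions by per-residue native-likeness")
print("(the language-model-style selector) consistently accelerates the search.")
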