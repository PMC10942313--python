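"""Run a full NSGA-II design simulation on the built-in toy two-state
problem and report how well the final population approximates the true
Pareto front.

The toy problem has L=6 designable positions over a 4-letter alphabet, two
conformational states with surrogate PSSM objectives, and half of the
positions in conflict between the states — so no single sequence can be
optimal for both, and the interesting output is the tradeoff front.
"""

from modesign.moea import RunConfig, fast_non_dominated_sort
from modesign.runner import run_design
from modesign.synthetic import enumerate_pareto_front, make_toy_problem

toy = make_toy_problem(L=6, A=4, conflict_fraction=0.5, seed=12)
print(f"toy wild type (two-state consensus): {toy.problem.reference_sequence}")
print(f"conflicting designed positions (0-based): {toy.conflict_positions}")

config = RunConfig(population_size=100, iterations=50, mutation_rate=0.3, seed=0)
history = run_design(toy.problem, config, toy.objective_specs(),
                     hv_reference=(0.0, 0.0))

final = history.final_population
metrics = history.records[-1].metrics
print(f"\nafter {config.iterations} iterations (population {config.population_size}):")
print(f"  mean native recovery:      {metrics['mean_recovery']:.3f}")
print(f"  front-0 hypervolume (ref (0,0)): {metrics['hv_front0']:.4f}")

obj = final.objective_matrix()
front0 = fast_non_dominated_sort(obj).fronts[0]
found = {final.members[i].designed_residues for i in front0}
true_seqs, _ = enumerate_pareto_front(toy)
coverage = len(found & set(true_seqs)) / len(true_seqs)
print(f"  non-dominated sequences found: {len(found)}")
print(f"  true Pareto set size (exhaustive over 4^6 = 4096): {len(true_seqs)}")
print(f"  coverage of the true front: {coverage:.0%}")
print("\nBoth objectives are negated saturating state scores in [-1, 0];")
print("a coverage near 100% means the optimizer recovered essentially the")
print("whole exact tradeoff front between the two conformational states.")
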