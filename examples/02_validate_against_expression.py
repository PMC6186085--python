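"""Validate model predictions against a synthetic two-condition experiment.

Generates a triplicate control-vs-treated expression experiment whose
differential-expression calls agree with the logical model predictions
for 75% of genes, runs the DE pipeline (Welch test, fold-change 1.5 and
raw p < 0.05 filter), classifies |E_mod - E_exp| per gene, and prints a
validation-summary row: correct / small error / large error percentages
with the binomial point-mass significance (null: three equiprobable
outcomes, success probability 1/3).
"""

from p53netval import (
    SynthExperimentSpec,
    classify_predictions,
    derive_eexp,
    differential_expression,
    generate_expression_experiment,
    map_genes_to_model,
    random_network,
    summarize,
)

net = random_network(n_nodes=100, edge_density=0.04, inhibition_fraction=0.3, seed=42)
spec = SynthExperimentSpec(network=net, concordance=0.75, effect_size=2.0,
                           noise_sd=0.1, n_replicates=5, seed=42)
matrix, truth = generate_expression_experiment(spec)

de = derive_eexp(differential_expression(matrix, "control", "treated"))
de = map_genes_to_model(de, net)
classes = classify_predictions(dict(truth["emod"]), de)
s = summarize(classes)

print(f"genes compared: {s.n_genes}")
print(f"correct predictions: {s.n_correct} ({s.pct_correct}%)")
print(f"small errors:        {s.n_small} ({s.pct_small}%)")
print(f"large errors:        {s.n_large} ({s.pct_large}%)")
print(f"significance (binomial point mass, p=1/3): {s.significance:.3e}")
print("\nThe correct fraction tracks the generator's 75% concordance;")
print("the tiny significance shows far more correct calls than chance.")
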