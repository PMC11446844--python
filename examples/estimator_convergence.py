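"""Connectome prior versus raw instrumental variables, at toy scale.

Simulates a 300-neuron network whose ground-truth weights are redrawn from
the connectome prior each replicate, stimulates the highest out-degree
neuron with white-noise laser drive (SNR = 10), and compares the raw IV
estimator with IV-Bayes as recording length grows. The full desk-scale
study (D = 2000, n up to 1e5) runs via scripts/acceptance.py.
"""

from effectome import ConvergenceConfig, convergence_experiment

cfg = ConvergenceConfig(
    d=300,
    sparsity=0.03,
    scale_s=5e-4,
    sample_sizes=(1_000, 10_000),
    n_replicates=3,
    seed=1,
)
result = convergence_experiment(cfg)
print(f"stimulated source neuron: {result.source}")
print(result.summary().to_string(index=False))
print(
    "\nRSS = summed squared error of the estimated outgoing weights of the\n"
    "stimulated neuron; R^2 = fraction of true-weight variance explained.\n"
    "IV-Bayes sits well below raw IV at every recording length because the\n"
    "prior suppresses noise on the overwhelming majority of weights that\n"
    "are anatomically zero."
)
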