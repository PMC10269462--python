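"""In-silico knockout: does the focal module survive losing its genus?

Removes (or scales down) Trichoderma, rebuilds the coated network with
identical parameters, and matches the original module against the new
partition by shared-node proportion.
"""

import warnings

from rhizonet import SyntheticScenario, generate_counts, knockout_experiment

warnings.filterwarnings("ignore")

scenario = SyntheticScenario(
    n_samples_per_group=30,
    groups=(("maize", "coated"), ("maize", "control")),
    seed=4,
)
counts, taxonomy, metadata = generate_counts(scenario)

results = knockout_experiment(counts, taxonomy, metadata, "Trichoderma", seed=0)
for mode, res in results.items():
    verdict = "persists" if res.persists else "dissolved"
    print(
        f"{mode:6s}: target module of {len(res.target_module)} nodes -> "
        f"shared proportion {res.match.shared_proportion:.2f} "
        f"(jaccard {res.match.jaccard:.2f}) -> {verdict}"
    )
print("-> deleting the genus dissolves the module it nucleated (its",
      "satellites cohere only through the inoculant), while common-factor",
      "scaling in reduce mode leaves rank correlations — hence the module —",
      "largely intact on noiseless synthetic data.")
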