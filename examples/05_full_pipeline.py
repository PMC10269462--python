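"""Run the orchestrated pipeline on the default study design and print
its one-page summary (networks, PERMANOVA, diversity tests, module-trait
correlations, knockout verdicts)."""

import warnings

from rhizonet.pipeline import RunConfig, report_summary, run_pipeline
from rhizonet.synthetic import SyntheticScenario

warnings.filterwarnings("ignore")

config = RunConfig(out_dir="scratch/example_run",
                   scenario=SyntheticScenario(), seed=42)
manifest = run_pipeline(config)
print(report_summary(config.out_dir))
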