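"""The full pipeline: tiers → imputation → selection → pooled report.

Runs a reduced-size end-to-end analysis (600 cases, shortened sampler) on
the default synthetic panel and prints the cross-tier report: a '+' marks a
pooled inclusion probability of 95% or above in that sparsity tier, and the
total column counts the tiers where the analyte qualified.
"""

import logging

from labsieve import GeneratorConfig, PipelineConfig, run_pipeline

logging.basicConfig(level=logging.WARNING)

config = PipelineConfig(
    base_seed=1,
    generator=GeneratorConfig(seed=1, n_cases=600),
    n_iter=4000,
    n_burn=1000,
)
result = run_pipeline(config)

cols = ["analyte"] + [f"tier_{t:g}" for t in result.report.tiers] + ["total"]
print(result.report.table[cols].head(10).to_string(index=False))
# The fully observed troponin analog (true standardized coefficient 2.0)
# is flagged in every tier; weaker true predictors (potassium, rdw, urea)
# appear as the sparser tiers admit them; null analytes stay unflagged.
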