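"""Run the complete pipeline end to end and print its report.

simulate (paired phantom scans + perfusion maps) -> segment -> extract
features -> two-loop LOO prediction -> ROC + agreement evaluation.  All
artifacts (NIfTI images/masks, cohort and score CSVs, ROC/agreement JSON,
manifest, report) land under one run directory; re-running with the same
config and seed reproduces identical file digests.

A 12-case run takes about half a minute; the 36-case default a few minutes.
"""

from pathlib import Path

from perfrad import RunConfig, run_pipeline

config = RunConfig(out_dir="pipeline_demo", seed=7, n_cases=12, n_nondfs=4)
manifest = run_pipeline(config)

print(Path(config.out_dir, "report.md").read_text())
print("stages completed:", ", ".join(manifest.stages))
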