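"""Run the whole analysis end to end and print the summary report.

simulate -> DE (both assays) -> network-propagation screen -> pair
discovery, with every stage seeded from one global seed; a rerun with the
same configuration is byte-identical. Equivalent shell command:
``mirlink all --outdir out --seed 7``.
"""

import tempfile
from pathlib import Path

from mirlink import NetpropConfig
from mirlink.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(netprop=NetpropConfig(n_perm=500), pair_n_perm=5000,
                     seed=7)
with tempfile.TemporaryDirectory() as tmp:
    report = run_pipeline(cfg, Path(tmp) / "out")
    print((Path(tmp) / "out" / "report.txt").read_text())
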