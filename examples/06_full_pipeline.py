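"""Run the whole pipeline from a single YAML config.

`pedscout run --config examples/run.yaml` does the same from the shell.
Here the config is copied into a temporary directory (its relative
`outdir` resolves next to the config), the pipeline runs end to end, and
the manifest reports each stage's outputs.
"""

import json
import shutil
import tempfile
from pathlib import Path

from pedscout.cli import run_all

src = Path(__file__).with_name("run.yaml")
with tempfile.TemporaryDirectory() as tmp:
    cfg = Path(tmp) / "run.yaml"
    shutil.copy(src, cfg)
    manifest = run_all(cfg)

print("config sha256:", manifest["config_sha256"][:16], "…")
print("funnel:", " -> ".join(str(c)
      for c in manifest["stages"]["prioritize"]["funnel_counts"]))
print("candidates:", manifest["stages"]["prioritize"]["n_candidates"])
print("case-exclusive shared ROH:", manifest["stages"]["roh"]["n_case_exclusive"])
print("stages run:", ", ".join(manifest["stages"]))
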