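"""One-call pipeline with manifest and planted-truth scoring.

``run_synthetic`` generates an atlas, runs every stage, writes all TSV
outputs plus a manifest with content hashes, and appends precision/recall
of the planted signal. The same run is available from the shell as
``tissuexpr synth --out <dir> --seed 1``.
"""

import json
import tempfile
import warnings
from pathlib import Path

import tissuexpr as tx

out = Path(tempfile.mkdtemp()) / "run"
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    manifest = tx.run_synthetic(tx.SynthConfig(
        seed=1, n_tissues=8, n_hkg=120, n_tsg=80, n_modules=2,
        module_size=40, n_background=500, n_inactive=150), out)

print("stages:")
for stage in manifest["stages"]:
    print(" ", json.dumps(stage))
print(f"\n{len(manifest['outputs'])} output files in {out}")
print("recovery vs planted truth:")
for key, value in manifest["recovery"].items():
    print(f"  {key}: {value if value is None else round(value, 4)}")
# Rerunning with the same seed reproduces every output hash exactly; the
# manifest alone is enough to verify a replication.
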