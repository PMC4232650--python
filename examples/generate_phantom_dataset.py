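"""Write a small synthetic fundus dataset (images, ground truth, manifest).

Run:  python examples/generate_phantom_dataset.py
"""

import dataclasses
import tempfile
from pathlib import Path

from retinoquant import PhantomSpec, make_cohort

out_dir = Path(tempfile.mkdtemp(prefix="retinoquant_phantoms_"))
moderate = PhantomSpec()
severe = dataclasses.replace(moderate, n_exudates=12, n_mas=28)
manifest, _ = make_cohort(moderate, severe, n_per_group=2, seed=0, out_dir=out_dir)

print(f"wrote {len(manifest)} phantoms under {out_dir}")
print()
print(manifest[["image_id", "group", "true_ratio", "true_ma_count"]].to_string(index=False))
print()
print("images/ holds the 685 x 584 PNG frames; truth/ holds per-image binary")
print("masks (exudates, disk, vessels) plus a JSON with microaneurysm centers")
print("and planted totals; manifest.csv is the cohort input for the CLI:")
print(f"  retinoquant cohort {out_dir / 'manifest.csv'}")
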