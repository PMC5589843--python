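"""Compare satellite values against the in-situ point samples.

Nearest-coincident matching, then standardized major axis regression,
Pearson correlation and median absolute error per variable, plus the
lake-level comparison of median chl-a.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _config import parse_config

from lakecoupling.pipeline import stage_validate

cfg = parse_config(__doc__)
stage_validate(cfg)
report = Path(cfg.out_dir) / "validation_report.txt"
if report.exists():
    print(report.read_text())
else:
    print("no in-situ data available; validation skipped")
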