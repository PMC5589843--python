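"""Compute the field of interannual Kendall correlations.

One tie-corrected tau per (pixel, 5-day day-of-year stratum) with at least
eight coincident years of paired observations.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _config import parse_config

from lakecoupling.pipeline import stage_correlate

cfg = parse_config(__doc__)
stage_correlate(cfg)
field = pd.read_csv(Path(cfg.out_dir) / "correlations.csv")
print(f"{len(field):,} stratum correlations; "
      f"{(field['p_value'] < 0.05).mean():.0%} nominally significant; "
      f"mean tau {field['tau'].mean():+.3f}")
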