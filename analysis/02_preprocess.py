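"""Reduce the archive to analysis resolution.

0.1-degree spatial medians, 5-day temporal medians, then an inner join
keeping only cells where both LST and chl-a are present.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _config import parse_config

from lakecoupling.pipeline import stage_preprocess

cfg = parse_config(__doc__)
stage_preprocess(cfg)
pairs = pd.read_csv(Path(cfg.out_dir) / "preprocessed.csv")
print(f"{len(pairs):,} coincident 0.1-degree / 5-day pairs across "
      f"{pairs['lake_id'].nunique()} lakes")
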