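"""Shared run configuration for the numbered analysis drivers.

Every driver operates on the same artifact directory (results/run by
default) so later stages read what earlier stages wrote; pass --out to work
elsewhere and --seed to reseed every stage.
"""

import argparse

from lakecoupling.io import PipelineConfig


def parse_config(description: str) -> PipelineConfig:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--config", default=None, help="YAML pipeline config")
    parser.add_argument("--out", default="results/run", help="artifact directory")
    parser.add_argument("--seed", type=int, default=None, help="master seed for all stages")
    args = parser.parse_args()
    cfg = PipelineConfig.from_yaml(args.config) if args.config else PipelineConfig()
    cfg.out_dir = args.out
    if args.seed is not None:
        cfg.seeds = {k: args.seed + i for i, k in enumerate(sorted(cfg.seeds))}
    cfg.validate()
    return cfg
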