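#!/usr/bin/env python
"""Simulate the field study: isotope, census, attribute and weight tables.

Writes a seeded synthetic data set with the study's design — nine social
groups with bimodal sizes straddling 17 members, 4–7 vibrissa samples per
focal individual, and weekly paired-morning weights — plus the truth record
of every latent parameter, under results/synthetic_data/.
"""

import argparse
from pathlib import Path

from isoniche.synthetic import SyntheticConfig, generate_to_dir


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/synthetic_data"))
    args = parser.parse_args()

    config = SyntheticConfig(seed=args.seed)
    paths = generate_to_dir(config, args.out)
    print(f"synthetic study written under {args.out} (seed {args.seed}):")
    for name, path in paths.items():
        print(f"  {name}: {path}")
    print(
        "the truth record stores group sizes, centroids, sampled fractions and "
        "the calibrated within-covariance scales; the configured group-size "
        f"effect on sqrt(RINI) is {config.group_size_effect_on_sqrt_rini}"
    )


if __name__ == "__main__":
    main()
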