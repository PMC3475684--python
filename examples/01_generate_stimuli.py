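"""Generate the 16-category dead-leaves stimulus set and save PNGs.

Renders a handful of images per category (pass --full for all 256), writes
them as 8-bit grayscale PNGs with a manifest CSV, and prints per-category
disk counts.  High disk counts for small-disk categories and low counts
for large-disk categories reflect the coverage-based stopping rule.
"""

import argparse
from pathlib import Path

from deadleaves import stimuli


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("stimulus_set"))
    parser.add_argument("--full", action="store_true", help="all 16 images/category")
    args = parser.parse_args()

    per_cat = 16 if args.full else 2
    images = stimuli.generate_stimulus_set(
        master_seed=args.seed, images_per_category=per_cat
    )
    manifest = stimuli.save_images(images, args.outdir)
    print(f"wrote {len(images)} PNGs + manifest.csv to {args.outdir}/")
    summary = manifest.groupby(
        ["category_id", "opacity_mode", "depth_mode", "size_class", "radius_distribution"]
    )["n_disks"].mean()
    print("\nmean disks per image (category settings -> compositing effort):")
    print(summary.to_string())


if __name__ == "__main__":
    main()
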