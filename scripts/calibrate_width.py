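"""Calibrate the default encoder base width against the published model
complexity (1.26e7 trainable parameters for the 512x512 configuration).

The architecture fixes how widths relate (stage doubling, x4 star
expansion, x16 bottleneck) but not their absolute scale; the printed
parameter count is the only constraint, so the default base width is the
integer whose total count lands closest to it.

Usage: python scripts/calibrate_width.py [--target 1.26e7]
"""

import argparse

from sdasnet import ModelConfig, build_model, count_parameters


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--target", type=float, default=1.26e7)
    ap.add_argument("--lo", type=int, default=16)
    ap.add_argument("--hi", type=int, default=48)
    args = ap.parse_args()
    best = None
    for bw in range(args.lo, args.hi + 1):
        n = count_parameters(build_model(ModelConfig(base_width=bw), seed=0))
        rel = (n - args.target) / args.target
        marker = ""
        if best is None or abs(rel) < abs(best[2]):
            best = (bw, n, rel)
            marker = " <-"
        print(f"base_width {bw:3d}  params {n:>12,}  {rel:+8.3%}{marker}")
    bw, n, rel = best
    print(f"\nbest: base_width={bw} ({n:,} parameters, {rel:+.3%} from target)")


if __name__ == "__main__":
    main()
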