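#!/usr/bin/env python
"""Reproduce the shipped fibrillar calibration.

Runs the documented calibration (seed 1, 32 Sobol starts, default
bounds) and prints the fitted parameters next to the values frozen in
``csfsink.pet``. Takes about a minute on one CPU.

Usage: python scripts/calibrate_defaults.py [--out calibration.json]
"""
from __future__ import annotations

import argparse
from pathlib import Path

from csfsink import KineticParams, Milestones, calibrate_fibrillar, calibrated_defaults


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-starts", type=int, default=32)
    ap.add_argument("--out", type=Path, default=None)
    args = ap.parse_args()

    res = calibrate_fibrillar(
        KineticParams(), Milestones(), n_starts=args.n_starts, seed=args.seed
    )
    print(f"converged: {res.converged}  loss: {res.loss:.3e} month^2")
    print(f"fitted:  {res.fparams}")
    print(f"washout: it={res.washout_it:.6g} iv={res.washout_iv:.6g}")
    fp, w_it, w_iv = calibrated_defaults()
    print(f"shipped: {fp}")
    print(f"washout: it={w_it:.6g} iv={w_iv:.6g}")
    if args.out:
        res.to_json(args.out)
        print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
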