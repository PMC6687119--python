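"""Regenerate the shipped Dynamic Fit coefficient tables.

Runs SCRE ensembles of the stochastic spatial cell model over an SR-Ca2+
ladder for each Ca2+-handling condition, fits the initiation-time and
duration distribution models per level, fits smooth curves over SR-Ca2+,
and writes the packed coefficient CSV consumed by
``srfsim.sampling.default_dynamic_fit_coefficients``.

Usage:  python scripts/build_dynamic_fit_coefficients.py [--fast]
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import pandas as pd

from srfsim.fitting import build_dynamic_fit
from srfsim.sampling import DynamicFitCoefficients
from srfsim.spatial import SpatialParams, generate_scre_ensemble

OUT = Path(__file__).resolve().parent.parent / "src" / "srfsim" / "data" / "dynamic_fit_coefficients.csv"

CASR_LEVELS = (0.90, 0.925, 0.95, 0.975, 1.00, 1.05, 1.15, 1.30)
CONDITIONS = {
    "control": SpatialParams(dims=(10, 8, 8)),
    "r_cru_cru": SpatialParams(dims=(10, 8, 8), r_cru_cru=True),
    "r_serca_ncx": SpatialParams(dims=(10, 8, 8), r_serca_ncx=True),
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fast", action="store_true", help="fewer runs per level")
    ap.add_argument("--runs", type=int, default=40)
    ap.add_argument("--seed", type=int, default=12345)
    args = ap.parse_args()
    runs = 15 if args.fast else args.runs

    merged = None
    for i, (cond, params) in enumerate(CONDITIONS.items()):
        print(f"[{cond}] ensembles: {len(CASR_LEVELS)} levels x {runs} runs",
              flush=True)
        ens = generate_scre_ensemble(
            params, CASR_LEVELS, n_runs_per_value=runs,
            seed=args.seed + 100 * i, duration=2000.0, condition=cond,
        )
        coeffs = build_dynamic_fit(ens, condition=cond)
        print(coeffs.to_frame().to_string(), flush=True)
        merged = coeffs if merged is None else DynamicFitCoefficients(
            tables={**merged.tables, **coeffs.tables},
            casr_range={**merged.casr_range, **coeffs.casr_range},
        )
    OUT.parent.mkdir(parents=True, exist_ok=True)
    merged.to_csv(OUT)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
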