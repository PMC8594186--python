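"""Asymptotic L1 growth dynamics from fitted rates.

Builds the 2x2 abundance dynamics matrix, reports the dominant
eigenvalue (insertions per nucleotide substitution), the per-generation
growth rate, the doubling time, and the equilibrium low/high activity
mix — for (a) the published best-fit rates and (b) this pipeline's own
re-fit of the synthetic bundle (results/fits.json from 02).  The six
rates can also be supplied explicitly on the command line.
"""

import argparse
import json
from pathlib import Path

from l1dynamics import (
    BisseParams,
    UnitConversion,
    asymptotic_growth,
    build_matrix,
    forward_integrate,
)
from l1dynamics.growth import format_report

ROOT = Path(__file__).resolve().parent.parent
PUBLISHED_BEST = BisseParams(10.0, 412.0, 0.0, 0.0, 31.0, 360.0)


def analyze(name: str, params: BisseParams, subst_rate: float) -> dict:
    m = build_matrix(params)
    res = asymptotic_growth(m, UnitConversion(subst_rate))
    traj = forward_integrate(m, [1.0, 1.0], t=max(0.1, 30.0 / max(abs(res.r_sub), 1.0)))
    print(f"\n== {name} ==")
    print(format_report(res))
    print(f"forward-integration cross-check slope: {traj.growth_rate():.4f}")
    return {
        "params": params.as_dict(),
        "matrix": m.m.tolist(),
        "r_sub": res.r_sub,
        "r_gen": res.r_gen,
        "doubling_time_generations": res.doubling_time,
        "fraction_high": res.fraction_high,
    }


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    for name in ("lambda0", "lambda1", "mu0", "mu1", "q01", "q10"):
        ap.add_argument(f"--{name}", type=float, default=None)
    ap.add_argument("--subst-rate", type=float, default=2.5e-8)
    args = ap.parse_args()

    out = {"published_best_fit": analyze("published best-fit rates", PUBLISHED_BEST, args.subst_rate)}

    explicit = {n: getattr(args, n) for n in ("lambda0", "lambda1", "mu0", "mu1", "q01", "q10")}
    if all(v is not None for v in explicit.values()):
        out["explicit"] = analyze("user-supplied rates", BisseParams(**explicit), args.subst_rate)

    fits_path = ROOT / "results" / "fits.json"
    if fits_path.exists():
        fits = json.loads(fits_path.read_text())
        best = min(fits, key=lambda f: f["aic"])
        refit = BisseParams(**best["params"])
        out["refit_best_model"] = analyze(
            f"re-fit of the synthetic bundle ({best['constraint']})", refit, args.subst_rate
        )

    path = ROOT / "results" / "growth.json"
    path.write_text(json.dumps(out, indent=1) + "\n")
    print(f"\nwrote {path}")


if __name__ == "__main__":
    main()
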