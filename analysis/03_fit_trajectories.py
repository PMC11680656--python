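#!/usr/bin/env python
"""Fit latent class mixed models for G = 1..6 trajectory classes.

Each candidate model has class-specific quadratic mean curves of rescaled
age on the log(x+1) intake scale, shared random intercept/slope/quadratic
effects and an intercept-only membership model, estimated by multistart
maximum likelihood (random perturbations of the 1-class solution plus a
warm start splitting the largest class of the previous fit).  Writes one
fit JSON per G under results/run.
"""

import argparse
from pathlib import Path

import pandas as pd

from alctraj.lcmm import TrajectoryData, TrajectorySpec, fit_multistart, warm_start_from

parser = argparse.ArgumentParser()
parser.add_argument("--data", default="results/run/data")
parser.add_argument("--out", default="results/run")
parser.add_argument("--classes", default="1,2,3,4,5,6")
parser.add_argument("--starts", type=int, default=6)
parser.add_argument("--seed", type=int, default=20250922)
args = parser.parse_args()

out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)
intakes = pd.read_csv(Path(args.data) / "intakes.csv")
ids = pd.read_csv(out / "trajectory_set_ids.csv")["subject_id"]
data = TrajectoryData.from_frame(intakes[intakes["subject_id"].isin(ids)])
print(f"trajectory set: {data.n_subjects} women, {data.n_obs} measures")

base = None
prev = None
for G in (int(c) for c in args.classes.split(",")):
    warm = [warm_start_from(prev)] if (prev is not None and prev.n_classes == G - 1) else None
    fit = fit_multistart(
        data, TrajectorySpec(G), n_starts=args.starts, warm_starts=warm,
        seed=args.seed + 1000 * G, base_fit=base,
    )
    if G == 1:
        base = fit
    fit.to_json(out / f"lcmm_fit_G{G}.json")
    print(f"G={G}: loglik={fit.loglik:.2f}, converged={fit.converged}, "
          f"shares={[round(s, 3) for s in sorted(fit.class_shares, reverse=True)]}")
    prev = fit
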