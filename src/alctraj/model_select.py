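"""Selection of the number of latent classes.

Candidates G = 1..G_max are compared on BIC, relative entropy, ICL and the
posterior classification, with two hard screening rules: no retained class
may hold less than 5% of the subjects (too few events for inference), and
the mean posterior probability among modally assigned subjects must be at
least 0.75 in every class.  Among surviving candidates the lowest BIC wins;
ICL and entropy are always reported alongside.

BIC counts subjects (not measurements), the convention for mixtures over
subjects.  Entropy is the relative form 1 - sum_i sum_g(-p_ig ln p_ig) /
(N ln G); ICL penalizes BIC by -2 sum_i ln p_i,modal(i) (so ICL >= BIC, with
equality only for a perfectly certain classification).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from alctraj.lcmm import LcmmFit, PosteriorMatrix


def bic(loglik: float, n_params: int, n_subjects: int) -> float:
    """Bayesian Information Criterion: -2 loglik + n_params ln(N)."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return -2.0 * loglik + n_params * np.log(n_subjects)


def entropy_measure(posteriors: PosteriorMatrix) -> float:
    """Relative entropy of the classification in [0, 1]; 1 = perfect separation.

    Defined as 1 - sum_i sum_g(-p_ig ln p_ig) / (N ln G) with 0 ln 0 = 0.
    Undefined for a single class.
    """
    probs = posteriors.probs
    N, G = probs.shape
    if G < 2:
        raise ValueError("entropy is undefined for a 1-class model")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log(probs), 0.0)
    return float(1.0 + plogp.sum() / (N * np.log(G)))


def icl(bic_value: float, posteriors: PosteriorMatrix) -> float:
    """Integrated Classification Likelihood criterion (classification-penalized BIC).

    ICL = BIC - 2 sum_i ln p_i,modal(i).  The sum is <= 0, so ICL >= BIC.
    """
    probs = posteriors.probs
    modal_p = probs[np.arange(len(probs)), posteriors.modal_class - 1]
    modal_p = np.clip(modal_p, 1e-300, None)
    return float(bic_value - 2.0 * np.log(modal_p).sum())


@dataclass
class SelectionReport:
    """Per-candidate criteria plus the chosen G and a textual rule trace."""

    candidates: list[dict] = field(default_factory=list)
    chosen_G: int | None = None
    trace: list[str] = field(default_factory=list)

    def add_candidate(self, fit: LcmmFit, posteriors: PosteriorMatrix | None, n_subjects: int):
        G = fit.n_classes
        b = bic(fit.loglik, fit.n_params, n_subjects)
        entry = {
            "G": G,
            "loglik": float(fit.loglik),
            "n_params": int(fit.n_params),
            "converged": bool(fit.converged),
            "BIC": float(b),
            "class_shares": fit.class_shares.tolist(),
            "smallest_class_share": float(fit.class_shares.min()),
        }
        if posteriors is not None and G >= 2:
            entry["entropy"] = entropy_measure(posteriors)
            entry["ICL"] = icl(b, posteriors)
            entry["mean_posterior_by_class"] = posteriors.mean_posterior_by_class.tolist()
            entry["modal_shares"] = posteriors.class_shares_modal().tolist()
        else:
            entry["entropy"] = None
            entry["ICL"] = float(b)
            entry["mean_posterior_by_class"] = [1.0]
            entry["modal_shares"] = [1.0]
        self.candidates.append(entry)
        return entry

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.candidates)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"candidates": self.candidates, "chosen_G": self.chosen_G, "trace": self.trace},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_text(self) -> str:
        lines = ["G  loglik        BIC          ICL          entropy  min_share  min_mean_post"]
        for c in self.candidates:
            post = c["mean_posterior_by_class"]
            min_post = np.nanmin([p for p in post if p is not None]) if post else float("nan")
            ent = "   --  " if c["entropy"] is None else f"{c['entropy']:7.3f}"
            lines.append(
                f"{c['G']}  {c['loglik']:12.2f}  {c['BIC']:11.2f}  {c['ICL']:11.2f}  "
                f"{ent}  {c['smallest_class_share']:9.3f}  {min_post:13.3f}"
            )
        lines.append(f"chosen G = {self.chosen_G}")
        lines.extend(self.trace)
        return "\n".join(lines)


def apply_selection_rules(
    report: SelectionReport,
    min_share: float = 0.05,
    min_mean_posterior: float = 0.75,
) -> SelectionReport:
    """Apply the class-size and posterior-quality screens, then pick the lowest BIC.

    Candidates with any class holding fewer than ``min_share`` of the
    subjects, or with mean posterior probability below
    ``min_mean_posterior`` in any modal class, are discarded (the 1-class
    model is exempt from both screens — it has one certain class).  The
    full decision trace is recorded.  If every candidate is discarded a
    descriptive failure lists the violations.
    """
    if not report.candidates:
        raise ValueError("no candidates to select among")
    survivors = []
    for c in report.candidates:
        reasons = []
        if c["G"] >= 2:
            if c["smallest_class_share"] < min_share:
                reasons.append(
                    f"smallest class share {c['smallest_class_share']:.3f} < {min_share}"
                )
            mean_post = [p for p in c["mean_posterior_by_class"] if p is not None and np.isfinite(p)]
            if mean_post and min(mean_post) < min_mean_posterior:
                reasons.append(
                    f"mean posterior {min(mean_post):.3f} < {min_mean_posterior} in some class"
                )
        if not c["converged"]:
            reasons.append("did not converge")
        if reasons:
            report.trace.append(f"G={c['G']}: discarded ({'; '.join(reasons)})")
        else:
            survivors.append(c)
            report.trace.append(f"G={c['G']}: retained (BIC={c['BIC']:.2f}, ICL={c['ICL']:.2f})")
    if not survivors:
        raise RuntimeError("all candidates discarded: " + " | ".join(report.trace))

    by_bic = min(survivors, key=lambda c: c["BIC"])
    by_icl = min(survivors, key=lambda c: c["ICL"])
    report.trace.append(f"BIC prefers G={by_bic['G']}; ICL prefers G={by_icl['G']}")
    if by_bic["G"] != by_icl["G"]:
        report.trace.append("criteria disagree; BIC is the deciding rule")
    report.chosen_G = int(by_bic["G"])
    report.trace.append(f"chosen G={report.chosen_G} by lowest BIC among retained candidates")
    return report
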