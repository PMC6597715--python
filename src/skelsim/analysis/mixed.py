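"""Random-effects regression of trial accuracy on model dissimilarities.

The model has crossed random intercepts for subject and object and the
(z-scored) model dissimilarities as fixed effects.  Each predictor's
significance is a likelihood-ratio test (df = 1) of the full model against
the model without that predictor, both fitted by maximum likelihood.

Two links are available:

* ``identity`` (default): a linear mixed model on the 0/1 accuracies (or on
  aggregated cell accuracies), fitted with statsmodels' ``MixedLM`` using
  variance components for the two crossed factors.
* ``logit``: a binomial GLMM fitted by lme4's ``glmer`` through ``Rscript``.
  Coefficients are then on the log-odds scale.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

_REQUIRED = ["subject", "object", "response"]


@dataclass
class MixedModelResult:
    link: str
    coefficients: dict  # predictor -> beta (model link scale)
    lrt_chi2: dict      # predictor -> LR statistic
    lrt_df: dict        # predictor -> constrained parameters (1)
    lrt_p: dict
    random_variances: dict  # "subject"/"object" -> variance estimate
    loglik: float


def _prepare(data: pd.DataFrame, predictors: list[str], link: str) -> pd.DataFrame:
    missing = [c for c in _REQUIRED + list(predictors) if c not in data.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    df = data[_REQUIRED + list(predictors)].copy()
    if link == "logit" and not df["response"].isin([0, 1]).all():
        raise ValueError("logit link requires a binary 0/1 response")
    for p in predictors:
        sd = df[p].std(ddof=0)
        if sd == 0:
            raise ValueError(f"constant predictor {p!r}")
        df[p] = (df[p] - df[p].mean()) / sd
    return df


def _fit_mixedlm(df: pd.DataFrame, predictors: list[str]):
    import statsmodels.formula.api as smf

    rhs = " + ".join(predictors) if predictors else "1"
    model = smf.mixedlm(
        f"response ~ {rhs}",
        df.assign(_all=1),
        groups="_all",
        re_formula="0",
        vc_formula={"subject": "0 + C(subject)", "object": "0 + C(object)"},
    )
    result = None
    for method in ("lbfgs", "bfgs", "cg"):
        result = model.fit(reml=False, method=method, maxiter=500, disp=False)
        if getattr(result, "converged", True):
            break
    return result


def exp2_mixed_model(
    data: pd.DataFrame,
    predictors: list[str],
    link: str = "identity",
) -> MixedModelResult:
    """Fit the crossed random-intercept model and LR-test each predictor.

    ``data`` needs columns ``subject``, ``object``, ``response`` plus one
    column per predictor (per-trial model dissimilarity values).
    """
    df = _prepare(data, predictors, link)
    if link == "identity":
        full = _fit_mixedlm(df, predictors)
        coef = {p: float(full.params[p]) for p in predictors}
        chi2, pvals, dfs = {}, {}, {}
        for p in predictors:
            reduced = _fit_mixedlm(df, [q for q in predictors if q != p])
            stat = max(0.0, 2.0 * (full.llf - reduced.llf))
            chi2[p] = float(stat)
            dfs[p] = 1
            pvals[p] = float(stats.chi2.sf(stat, df=1))
        vcomp = dict(zip(full.model.exog_vc.names, np.asarray(full.vcomp, dtype=float)))
        return MixedModelResult(
            "identity", coef, chi2, dfs, pvals,
            {k: float(v) for k, v in vcomp.items()}, float(full.llf),
        )
    if link == "logit":
        return _glmer_lrt(df, predictors)
    raise ValueError(f"unknown link {link!r}")


_R_TEMPLATE = """
suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
d <- read.csv("{csv}")
d$subject <- factor(d$subject); d$object <- factor(d$object)
preds <- c({preds})
rhs <- paste(c(preds, "(1|subject)", "(1|object)"), collapse=" + ")
full <- glmer(as.formula(paste("response ~", rhs)), data=d, family=binomial)
out <- list(loglik=as.numeric(logLik(full)),
            coef=as.list(fixef(full)),
            vc=as.list(unlist(lapply(VarCorr(full), function(m) m[1,1]))),
            lrt=list())
for (p in preds) {{
  rr <- paste(c(setdiff(preds, p), "(1|subject)", "(1|object)"), collapse=" + ")
  red <- glmer(as.formula(paste("response ~", rr)), data=d, family=binomial)
  out$lrt[[p]] <- max(0, 2 * (as.numeric(logLik(full)) - as.numeric(logLik(red))))
}}
cat(toJSON(out, auto_unbox=TRUE, digits=12))
"""


def _glmer_lrt(df: pd.DataFrame, predictors: list[str]) -> MixedModelResult:
    with tempfile.TemporaryDirectory() as tmp:
        csv = Path(tmp) / "trials.csv"
        df.to_csv(csv, index=False)
        script = _R_TEMPLATE.format(
            csv=csv, preds=", ".join(f'"{p}"' for p in predictors)
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=600
        )
        if proc.returncode != 0:
            raise RuntimeError(f"glmer backend failed:\n{proc.stderr[-2000:]}")
        payload = json.loads(proc.stdout)
    chi2 = {p: float(payload["lrt"][p]) for p in predictors}
    return MixedModelResult(
        "logit",
        {p: float(payload["coef"][p]) for p in predictors},
        chi2,
        {p: 1 for p in predictors},
        {p: float(stats.chi2.sf(chi2[p], df=1)) for p in predictors},
        {k: float(v) for k, v in payload["vc"].items()},
        float(payload["loglik"]),
    )
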