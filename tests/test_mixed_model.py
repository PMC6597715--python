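"""Crossed random-intercept regression and its likelihood-ratio tests."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from skelsim.analysis import exp2_mixed_model

pytestmark = pytest.mark.filterwarnings("ignore::Warning")


def synthetic_cells(
    slope, n_subjects=35, n_objects=18, n_reps=18,
    subject_sd=0.3, object_sd=0.2, seed=0,
):
    """Aggregated accuracy per subject x object with a logistic dependence
    on a per-object predictor."""
    rng = np.random.default_rng(seed)
    x_obj = np.linspace(-1.5, 1.5, n_objects)
    subj_fx = rng.normal(0, subject_sd, n_subjects)
    obj_fx = rng.normal(0, object_sd, n_objects)
    rows = []
    for s in range(n_subjects):
        for o in range(n_objects):
            logit = 1.2 + slope * x_obj[o] + subj_fx[s] + obj_fx[o]
            p = 1.0 / (1.0 + np.exp(-logit))
            acc = rng.binomial(n_reps, p) / n_reps
            rows.append(dict(subject=s, object=o, x=x_obj[o], response=acc))
    return pd.DataFrame(rows)


def test_negative_slope_recovered_significant():
    df = synthetic_cells(slope=-0.9, seed=1)
    res = exp2_mixed_model(df, ["x"])
    assert res.coefficients["x"] < 0
    assert res.lrt_chi2["x"] > 3.84
    assert res.lrt_p["x"] < 0.05
    assert res.lrt_df["x"] == 1


def test_permuted_predictor_null_calibration():
    """With the predictor shuffled across cells, LRT p-values are roughly
    uniform (checked through the rejection rate and the mean p)."""
    rng = np.random.default_rng(2)
    hits, ps = 0, []
    reps = 40
    for i in range(reps):
        df = synthetic_cells(slope=0.0, n_subjects=12, n_objects=10, seed=100 + i)
        df["x"] = rng.permutation(df["x"].to_numpy())
        res = exp2_mixed_model(df, ["x"])
        ps.append(res.lrt_p["x"])
        hits += res.lrt_p["x"] < 0.05
    assert hits / reps <= 0.175
    assert 0.3 <= np.mean(ps) <= 0.7


def test_zero_random_variance_matches_ols():
    """Without subject/object effects the mixed fit reduces to plain OLS."""
    rng = np.random.default_rng(3)
    df = synthetic_cells(slope=-0.6, subject_sd=0.0, object_sd=0.0, seed=4)
    res = exp2_mixed_model(df, ["x"])
    x = (df["x"] - df["x"].mean()) / df["x"].std(ddof=0)
    design = np.column_stack([np.ones(len(df)), x])
    beta = np.linalg.lstsq(design, df["response"], rcond=None)[0]
    assert res.coefficients["x"] == pytest.approx(beta[1], abs=1e-4)


def test_two_predictors_partial_out_shared_variance():
    rng = np.random.default_rng(5)
    df = synthetic_cells(slope=-0.9, seed=6)
    df["shadow"] = 0.7 * df["x"] + rng.normal(0, 1.0, len(df))
    res = exp2_mixed_model(df, ["x", "shadow"])
    assert res.lrt_chi2["x"] > res.lrt_chi2["shadow"]
    assert res.lrt_p["x"] < 0.05


def test_logit_link_requires_binary():
    df = synthetic_cells(slope=-0.5, seed=7)
    with pytest.raises(ValueError, match="binary"):
        exp2_mixed_model(df, ["x"], link="logit")


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_identity_lrt_agrees_with_lmer_oracle():
    """Cross-check the maximum-likelihood LRT against lme4's lmer."""
    df = synthetic_cells(slope=-0.8, n_subjects=10, n_objects=8, seed=8)
    res = exp2_mixed_model(df, ["x"])
    import json as _json
    import tempfile
    from pathlib import Path

    rcode = """
    suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
    d <- read.csv("%s")
    d$x <- (d$x - mean(d$x)) / (sd(d$x) * sqrt((nrow(d)-1)/nrow(d)))
    full <- lmer(response ~ x + (1|subject) + (1|object), data=d, REML=FALSE)
    red  <- lmer(response ~ 1 + (1|subject) + (1|object), data=d, REML=FALSE)
    cat(toJSON(list(chi2=2*(as.numeric(logLik(full)) - as.numeric(logLik(red))),
                    beta=as.numeric(fixef(full)["x"])), auto_unbox=TRUE, digits=10))
    """
    with tempfile.TemporaryDirectory() as tmp:
        csv = Path(tmp) / "d.csv"
        df.to_csv(csv, index=False)
        out = subprocess.run(
            ["Rscript", "-e", rcode % csv], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        oracle = _json.loads(out.stdout)
    assert res.lrt_chi2["x"] == pytest.approx(oracle["chi2"], abs=0.1)
    assert res.coefficients["x"] == pytest.approx(oracle["beta"], abs=1e-3)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_logit_backend_recovers_sign():
    rng = np.random.default_rng(9)
    rows = []
    for s in range(10):
        for o in range(8):
            x = (o - 4) / 2
            p = 1.0 / (1.0 + np.exp(-(1.0 - 0.9 * x)))
            for _ in range(6):
                rows.append(dict(subject=s, object=o, x=x, response=int(rng.random() < p)))
    df = pd.DataFrame(rows)
    res = exp2_mixed_model(df, ["x"], link="logit")
    assert res.link == "logit"
    assert res.coefficients["x"] < 0
    assert res.lrt_chi2["x"] > 3.84
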