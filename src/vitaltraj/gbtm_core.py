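"""Finite-mixture trajectory model over multichannel vital-sign series.

Each latent group g owns, per channel v, a polynomial mean curve
``mu_gv(t) = b0 + b1*t (+ b2*t^2)`` and a residual SD ``sigma_gv``; a
patient's component density is the product of independent normals over the
(channel, time) cells actually observed — missing cells contribute
nothing — and the cohort likelihood is the pi-weighted mixture. Fitting is
EM from multiple starts; model comparison uses BIC.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.special import logsumexp

from .channels import CHANNELS
from .preprocess import PatientSeries, StandardizationRecord

LOG_2PI = math.log(2.0 * math.pi)

#: Residual SDs are clipped below this (standardized units) to keep the
#: mixture likelihood bounded.
SIGMA_FLOOR = 1e-3


class FitError(RuntimeError):
    """Raised when the mixture cannot be fitted (singularity, no start converged)."""


@dataclass(frozen=True)
class GbtmSpec:
    """Structural specification of the mixture to fit."""

    n_groups: int
    orders: dict[str, int]  # channel -> polynomial order (1 linear, 2 quadratic)
    variance_mode: str = "group"  # "group" | "shared"

    def __post_init__(self):
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        for ch, order in self.orders.items():
            if order not in (1, 2):
                raise ValueError(f"order for {ch} must be 1 or 2, got {order}")
        if self.variance_mode not in ("group", "shared"):
            raise ValueError("variance_mode must be 'group' or 'shared'")

    def n_params(self) -> int:
        G = self.n_groups
        mean_params = sum(G * (order + 1) for order in self.orders.values())
        var_params = (G if self.variance_mode == "group" else 1) * len(self.orders)
        return (G - 1) + mean_params + var_params


@dataclass
class GbtmModel:
    """A fitted mixture: mixing weights, per-group/channel curves and SDs."""

    spec: GbtmSpec
    mixing: np.ndarray  # (G,)
    coefs: dict[str, np.ndarray]  # channel -> (G, order+1)
    sigmas: dict[str, np.ndarray]  # channel -> (G,)
    loglik: float = float("nan")
    n_patients: int = 0
    converged: bool = False
    n_iter: int = 0
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return self.spec.n_groups

    @property
    def n_params(self) -> int:
        return self.spec.n_params()


@dataclass(frozen=True)
class PosteriorAssignment:
    """Per-patient posterior membership vector and its modal group."""

    patient_id: str
    posterior: np.ndarray  # (G,), sums to 1
    modal_group: int
    max_posterior: float


def group_mean(beta: np.ndarray, t: np.ndarray | float) -> np.ndarray | float:
    """Evaluate ``b0 + b1*t (+ b2*t^2)`` at time(s) ``t``."""
    beta = np.asarray(beta, float)
    return np.polyval(beta[::-1], t)


def _poly_design(times: np.ndarray, order: int) -> np.ndarray:
    return np.vander(np.asarray(times, float), N=order + 1, increasing=True)


@dataclass
class _Design:
    """Flattened observation arrays, precomputed once per fit."""

    patient_ids: list[str]
    n: int
    channels: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    # channel -> (X design matrix, y values, patient index)


def build_design(series_set: Sequence[PatientSeries], orders: dict[str, int]) -> _Design:
    ids = [s.patient_id for s in series_set]
    channels: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for ch, order in orders.items():
        ts, ys, ps = [], [], []
        for i, s in enumerate(series_set):
            if ch not in s.observed:
                continue
            t, v = s.observed[ch]
            ts.append(t)
            ys.append(v)
            ps.append(np.full(len(t), i))
        if not ts:
            continue
        t_all = np.concatenate(ts)
        channels[ch] = (
            _poly_design(t_all, order),
            np.concatenate(ys),
            np.concatenate(ps).astype(np.intp),
        )
    return _Design(patient_ids=ids, n=len(ids), channels=channels)


def _component_loglik(design: _Design, coefs, sigmas, G: int) -> np.ndarray:
    """(n, G) matrix of per-patient per-group component log-densities."""
    comp = np.zeros((design.n, G))
    for ch, (X, y, pidx) in design.channels.items():
        mus = X @ coefs[ch].T  # (m, G)
        sig = sigmas[ch]  # (G,)
        resid = y[:, None] - mus
        ll = -0.5 * (LOG_2PI + 2.0 * np.log(sig)[None, :]) \
            - resid ** 2 / (2.0 * sig[None, :] ** 2)
        for g in range(G):
            comp[:, g] += np.bincount(pidx, weights=ll[:, g], minlength=design.n)
    return comp


def _posterior_matrix(comp: np.ndarray, mixing: np.ndarray) -> tuple[np.ndarray, float]:
    """Normalized posteriors and total log-likelihood, via log-sum-exp."""
    logw = comp + np.log(mixing)[None, :]
    totals = logsumexp(logw, axis=1)
    post = np.exp(logw - totals[:, None])
    return post, float(np.sum(totals))


def patient_loglik(model: GbtmModel, series: PatientSeries) -> tuple[np.ndarray, float]:
    """Per-group component log-densities and total log mixture density.

    Stable for densities spanning hundreds of orders of magnitude
    (log-sum-exp); unobserved cells contribute nothing.
    """
    design = build_design([series], model.spec.orders)
    comp = _component_loglik(design, model.coefs, model.sigmas, model.n_groups)[0]
    total = float(logsumexp(comp + np.log(model.mixing)))
    return comp, total


def e_step(model: GbtmModel, series_set: Sequence[PatientSeries]) -> list[PosteriorAssignment]:
    """Posterior membership ``post_g ∝ pi_g * component_g`` per patient."""
    design = build_design(series_set, model.spec.orders)
    comp = _component_loglik(design, model.coefs, model.sigmas, model.n_groups)
    post, _ = _posterior_matrix(comp, model.mixing)
    return [
        PosteriorAssignment(
            patient_id=design.patient_ids[i],
            posterior=post[i],
            modal_group=int(np.argmax(post[i])),
            max_posterior=float(np.max(post[i])),
        )
        for i in range(design.n)
    ]


def _m_step_design(
    design: _Design,
    post: np.ndarray,
    spec: GbtmSpec,
    sigma_floor: float = SIGMA_FLOOR,
):
    G = spec.n_groups
    mixing = post.mean(axis=0)
    coefs: dict[str, np.ndarray] = {}
    sigmas: dict[str, np.ndarray] = {}
    for ch, (X, y, pidx) in design.channels.items():
        p = X.shape[1]
        beta = np.empty((G, p))
        ssq = np.empty(G)
        wsum = np.empty(G)
        for g in range(G):
            w = post[pidx, g]
            sw = np.sqrt(w)
            A = X * sw[:, None]
            b = y * sw
            sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
            if rank < p:
                raise FitError(
                    f"singular weighted design for channel {ch}, group {g} "
                    f"(rank {rank} < {p}); not enough distinct times"
                )
            beta[g] = sol
            r = y - X @ sol
            ssq[g] = float(np.sum(w * r ** 2))
            wsum[g] = float(np.sum(w))
        if spec.variance_mode == "shared":
            sig = np.full(G, math.sqrt(max(ssq.sum() / wsum.sum(), sigma_floor ** 2)))
        else:
            sig = np.sqrt(np.maximum(ssq / wsum, sigma_floor ** 2))
        coefs[ch] = beta
        sigmas[ch] = sig
    return mixing, coefs, sigmas


def m_step(
    series_set: Sequence[PatientSeries],
    posteriors: np.ndarray,
    spec: GbtmSpec,
    sigma_floor: float = SIGMA_FLOOR,
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Weighted-least-squares parameter update given posterior weights.

    Returns ``(mixing, coefs, sigmas)``: mixing = mean posterior, beta by
    WLS with patient weights, sigma^2 = posterior-weighted mean squared
    residual (pooled across groups in "shared" mode), clipped at the floor.
    """
    design = build_design(series_set, spec.orders)
    return _m_step_design(design, np.asarray(posteriors, float), spec, sigma_floor)


def _init_posteriors(design: _Design, series_set, G: int, start: int,
                     rng: np.random.Generator) -> np.ndarray:
    n = design.n
    if G == 1:
        return np.ones((n, 1))
    if start == 0:
        # k-means-style split on per-patient channel means (missing ->
        # column mean), softened so no group starts empty-handed.
        chans = [ch for ch in CHANNELS if ch in design.channels]
        feats = np.full((n, len(chans)), np.nan)
        for j, ch in enumerate(chans):
            for i, s in enumerate(series_set):
                if ch in s.observed:
                    feats[i, j] = np.mean(s.observed[ch][1])
        col_mean = np.nanmean(feats, axis=0)
        inds = np.where(np.isnan(feats))
        feats[inds] = np.take(col_mean, inds[1])
        sd = feats.std(axis=0)
        sd[sd == 0] = 1.0
        feats = (feats - feats.mean(axis=0)) / sd
        _, labels = kmeans2(feats, G, minit="++", seed=rng)
        post = np.full((n, G), 0.1 / G)
        post[np.arange(n), labels] += 0.9
        return post / post.sum(axis=1, keepdims=True)
    return rng.dirichlet(np.ones(G), size=n)


def _run_em(design: _Design, post: np.ndarray, spec: GbtmSpec, max_iter: int,
            tol: float, sigma_floor: float):
    """One EM run; returns (model-or-None, status string)."""
    n = design.n
    G = spec.n_groups
    trace: list[float] = []
    prev = None
    mixing = coefs = sigmas = None
    converged = False
    for it in range(1, max_iter + 1):
        mixing, coefs, sigmas = _m_step_design(design, post, spec, sigma_floor)
        if G > 1 and np.any(mixing < 1.0 / (2 * n)):
            return None, f"degenerate (empty group at iter {it})"
        comp = _component_loglik(design, coefs, sigmas, G)
        post, ll = _posterior_matrix(comp, mixing)
        trace.append(ll)
        if prev is not None and abs(ll - prev) < tol:
            converged = True
            break
        prev = ll
    if not converged:
        return None, f"no convergence in {max_iter} iterations"
    model = GbtmModel(
        spec=spec, mixing=mixing, coefs=coefs, sigmas=sigmas,
        loglik=trace[-1], n_patients=n, converged=True,
        n_iter=len(trace), loglik_trace=trace,
    )
    return model, "converged"


def fit(
    series_set: Sequence[PatientSeries],
    spec: GbtmSpec,
    n_starts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    sigma_floor: float = SIGMA_FLOOR,
) -> GbtmModel:
    """Fit by EM from ``n_starts`` initializations; keep the best converged run.

    Start 0 seeds posteriors from a k-means split of per-patient channel
    means; further starts draw Dirichlet-random posteriors. A start whose
    mixing weight falls below 1/(2n) is discarded as degenerate. Fully
    deterministic given ``seed``. Raises :class:`FitError` when no start
    converges.
    """
    if not series_set:
        raise ValueError("empty series set")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    design = build_design(series_set, spec.orders)
    n_starts_eff = 1 if spec.n_groups == 1 else n_starts

    best: GbtmModel | None = None
    statuses: list[str] = []
    for start in range(n_starts_eff):
        post = _init_posteriors(design, series_set, spec.n_groups, start, rng)
        try:
            model, status = _run_em(design, post, spec, max_iter, tol, sigma_floor)
        except FitError as exc:
            if spec.n_groups == 1:
                raise
            model, status = None, f"failed ({exc})"
        statuses.append(f"start {start}: {status}")
        if model is not None and (best is None or model.loglik > best.loglik):
            best = model
    if best is None:
        raise FitError(
            "no EM start converged:\n  " + "\n  ".join(statuses)
        )
    return best


def bic(model: GbtmModel, n_patients: int | None = None) -> float:
    """Bayesian information criterion, ``-2*loglik + k*ln(n)``; lower is better."""
    n = model.n_patients if n_patients is None else n_patients
    return -2.0 * model.loglik + model.n_params * math.log(n)


def average_posterior_probability(
    assignments: Sequence[PosteriorAssignment], G: int
) -> np.ndarray:
    """Mean max-posterior among patients modally assigned to each group.

    Groups with no modal members get NaN (flagged as undefined).
    """
    if not assignments:
        raise ValueError("no assignments")
    app = np.full(G, np.nan)
    for g in range(G):
        probs = [a.max_posterior for a in assignments if a.modal_group == g]
        if probs:
            app[g] = float(np.mean(probs))
    return app


def permute_groups(model: GbtmModel, perm: Sequence[int]) -> GbtmModel:
    """Relabel groups by ``perm`` (new index g takes old index perm[g])."""
    perm = np.asarray(perm, int)
    return GbtmModel(
        spec=model.spec,
        mixing=model.mixing[perm],
        coefs={ch: b[perm] for ch, b in model.coefs.items()},
        sigmas={ch: s[perm] for ch, s in model.sigmas.items()},
        loglik=model.loglik,
        n_patients=model.n_patients,
        converged=model.converged,
        n_iter=model.n_iter,
        loglik_trace=list(model.loglik_trace),
    )


SCHEMA_VERSION = 1


def model_to_dict(model: GbtmModel,
                  std_record: StandardizationRecord | None = None) -> dict:
    """Serializable document; includes natural-unit curves when a
    standardization record is supplied."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "spec": {
            "n_groups": model.spec.n_groups,
            "orders": dict(model.spec.orders),
            "variance_mode": model.spec.variance_mode,
        },
        "mixing": model.mixing.tolist(),
        "coefs": {ch: b.tolist() for ch, b in model.coefs.items()},
        "sigmas": {ch: s.tolist() for ch, s in model.sigmas.items()},
        "loglik": model.loglik,
        "bic": bic(model),
        "n_params": model.n_params,
        "n_patients": model.n_patients,
        "converged": model.converged,
        "n_iter": model.n_iter,
    }
    if std_record is not None:
        doc["standardization"] = std_record.to_dict()
        doc["coefs_natural"] = {
            ch: [std_record.invert_coefficients(ch, np.asarray(b)).tolist()
                 for b in model.coefs[ch]]
            for ch in model.coefs
        }
        doc["sigmas_natural"] = {
            ch: (model.sigmas[ch] * std_record.sds[ch]).tolist()
            for ch in model.sigmas
        }
    return doc


def model_from_dict(doc: dict) -> GbtmModel:
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {doc.get('schema_version')}")
    spec = GbtmSpec(
        n_groups=int(doc["spec"]["n_groups"]),
        orders={k: int(v) for k, v in doc["spec"]["orders"].items()},
        variance_mode=doc["spec"]["variance_mode"],
    )
    return GbtmModel(
        spec=spec,
        mixing=np.asarray(doc["mixing"], float),
        coefs={ch: np.asarray(b, float) for ch, b in doc["coefs"].items()},
        sigmas={ch: np.asarray(s, float) for ch, s in doc["sigmas"].items()},
        loglik=float(doc["loglik"]),
        n_patients=int(doc["n_patients"]),
        converged=bool(doc["converged"]),
        n_iter=int(doc["n_iter"]),
    )


def save_model(model: GbtmModel, path: str | Path,
               std_record: StandardizationRecord | None = None) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model, std_record), indent=2))


def load_model(path: str | Path) -> GbtmModel:
    return model_from_dict(json.loads(Path(path).read_text()))
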