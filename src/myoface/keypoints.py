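"""Estimation of facial keypoint displacements from muscle activations.

Three estimators are implemented and compared:

* **SMSM** — a skin-musculoskeletal model in which each facial keypoint sits
  at the equilibrium of a linear skin spring (stiffness ``KH``) and one or
  two muscle springs whose stiffness ``k0 + k1*u`` and rest-length offset
  ``l0 + l1*u`` depend on the muscle activation ``u`` (Mykin muscle model).
  For a single-muscle system the equilibrium displacement is::

      dl = (k0 + k1*u) * (l0 + l1*u) / (KH + k0 + k1*u)

  For a double-muscle system (two muscles i acting on one point, with
  projection coefficients ``a_i`` and geometry coefficients ``lambda_i``)::

      dl = sum_i a_i*(k0_i + k1_i*u_i)*(l0_i + l1_i*u_i)
           / (KH + sum_i a_i*lambda_i*(k0_i + k1_i*u_i))

* **LRM** — an ordinary multivariate linear regression from the seven muscle
  activations to the five keypoint displacements, ``dL = W_lrm @ U``.

* **SMSM-LRM** — the hybrid ``dL = W @ smsm_forward(p, U)``: a 5x5 linear
  recombination of the per-keypoint SMSM outputs that captures skin coupling
  between keypoints which the local spring systems ignore.

Muscle-to-keypoint wiring is anatomically fixed: outer frontalis drives the
outer eyebrow, levator labii superioris alaeque nasi the nose point,
mentalis the chin; the mouth corner is a double system of zygomaticus major
and depressor anguli oris, the inner eyebrow of inner frontalis and
corrugator supercilii.

Spring parameters (and the hybrid's W) are fitted by full-batch gradient
descent with the Adam optimizer on the mean squared displacement error,
with ``k0``/``k1`` kept positive through a soft-plus reparameterization and
``KH`` held fixed.  The LRM has an exact least-squares solution which is
used by default; an Adam path is available for parity.  Because the product
``(k0 + k1*u)(l0 + l1*u)`` is invariant under reciprocal rescaling of its
factors, individual spring constants are not identifiable -- only predicted
displacements are; fitting quality is therefore always judged on
predictions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import KEYPOINTS, MUSCLES

DEFAULT_KH = 100.0  # skin stiffness, N/m

#: keypoint -> driving muscle for single-muscle systems
SINGLE_SYSTEMS: dict[str, str] = {
    "outer_eyebrow": "OF",
    "nose": "LLSAN",
    "chin": "Me",
}
#: keypoint -> (muscle, muscle) for double-muscle systems
DOUBLE_SYSTEMS: dict[str, tuple[str, str]] = {
    "mouth_corner": ("ZM", "DAO"),
    "inner_eyebrow": ("IF", "CS"),
}

_MUSCLE_IDX = {m: i for i, m in enumerate(MUSCLES)}
_DEN_FLOOR_FRAC = 1e-6      # denominator must stay above this fraction of KH
_ACTIVATION_BOX = (0.0, 1.5)  # admissible activation range for the guard


@dataclass
class SpringParams:
    """Mykin spring: stiffness k0 + k1*u, rest-length offset l0 + l1*u."""

    k0: float
    k1: float
    l0: float
    l1: float


@dataclass
class MuscleMember(SpringParams):
    """One muscle of a double system, with projection a and geometry lambda."""

    a: float = 1.0
    lam: float = 1.0


@dataclass
class SMSMParameters:
    """Full parameter set of the five keypoint spring systems."""

    singles: dict[str, SpringParams]
    doubles: dict[str, tuple[MuscleMember, MuscleMember]]
    KH: float = DEFAULT_KH

    def __post_init__(self):
        if self.KH <= 0:
            raise ValueError("KH must be positive")
        if set(self.singles) != set(SINGLE_SYSTEMS):
            raise ValueError("singles must cover exactly the single-muscle keypoints")
        if set(self.doubles) != set(DOUBLE_SYSTEMS):
            raise ValueError("doubles must cover exactly the double-muscle keypoints")
        for name, p in self.singles.items():
            if p.k0 <= 0 or p.k1 < 0:
                raise ValueError(f"non-positive stiffness in single system {name}")
        lo, hi = _ACTIVATION_BOX
        floor = _DEN_FLOOR_FRAC * self.KH
        for name, members in self.doubles.items():
            for p in members:
                if p.k0 <= 0 or p.k1 < 0:
                    raise ValueError(f"non-positive stiffness in double system {name}")
            # denominator is bilinear in (u1, u2); extrema sit at box corners
            for u1, u2 in itertools.product((lo, hi), repeat=2):
                den = self.KH + sum(
                    p.a * p.lam * (p.k0 + p.k1 * u)
                    for p, u in zip(members, (u1, u2))
                )
                if den < floor:
                    raise ValueError(
                        f"denominator of {name} drops to {den:.3g} at u=({u1},{u2})"
                    )


def smsm_single_displacement(p: SpringParams, KH: float, u) -> np.ndarray:
    """Equilibrium displacement of a single-muscle system (vectorized in u)."""
    u = np.asarray(u, dtype=float)
    g = p.k0 + p.k1 * u
    den = KH + g
    if np.any(den < _DEN_FLOOR_FRAC * KH):
        raise ValueError("equilibrium denominator below positivity floor")
    return g * (p.l0 + p.l1 * u) / den


def smsm_double_displacement(members: tuple[MuscleMember, MuscleMember],
                             KH: float, u_pair) -> np.ndarray:
    """Equilibrium displacement of a double-muscle system.

    ``u_pair`` is (u1, u2), scalars or arrays broadcast over time.
    """
    num = 0.0
    den = np.asarray(KH, dtype=float)
    for p, u in zip(members, u_pair):
        u = np.asarray(u, dtype=float)
        g = p.k0 + p.k1 * u
        num = num + p.a * g * (p.l0 + p.l1 * u)
        den = den + p.a * p.lam * g
    if np.any(den < _DEN_FLOOR_FRAC * KH):
        raise ValueError("equilibrium denominator below positivity floor")
    return num / den


def smsm_forward(params: SMSMParameters, U: np.ndarray) -> np.ndarray:
    """Displacements of the 5 keypoints from 7-muscle activations (7 x T)."""
    U = np.asarray(U, dtype=float)
    if U.shape[0] != len(MUSCLES):
        raise ValueError(f"U must have {len(MUSCLES)} rows (muscles)")
    out = np.empty((len(KEYPOINTS), U.shape[1]))
    for row, kp in enumerate(KEYPOINTS):
        if kp in SINGLE_SYSTEMS:
            u = U[_MUSCLE_IDX[SINGLE_SYSTEMS[kp]]]
            out[row] = smsm_single_displacement(params.singles[kp], params.KH, u)
        else:
            m1, m2 = DOUBLE_SYSTEMS[kp]
            out[row] = smsm_double_displacement(
                params.doubles[kp], params.KH,
                (U[_MUSCLE_IDX[m1]], U[_MUSCLE_IDX[m2]]),
            )
    return out


def lrm_predict(W_lrm: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Linear-regression displacement estimate, ``W_lrm @ U`` (5x7 @ 7xT)."""
    W_lrm = np.asarray(W_lrm, dtype=float)
    U = np.asarray(U, dtype=float)
    if W_lrm.shape != (len(KEYPOINTS), len(MUSCLES)) or U.shape[0] != len(MUSCLES):
        raise ValueError("expected W_lrm of shape 5x7 and U of shape 7xT")
    return W_lrm @ U


def hybrid_predict(params: SMSMParameters, W: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Hybrid estimate: 5x5 recombination of the SMSM keypoint outputs."""
    W = np.asarray(W, dtype=float)
    if W.shape != (len(KEYPOINTS), len(KEYPOINTS)):
        raise ValueError("W must be 5x5")
    return W @ smsm_forward(params, U)


# ---------------------------------------------------------------------------
# parameter vector <-> structured parameters (soft-plus reparameterization)
# ---------------------------------------------------------------------------

_SINGLE_ORDER = ("outer_eyebrow", "nose", "chin")
_DOUBLE_ORDER = ("mouth_corner", "inner_eyebrow")
_N_SPRING = 3 * 4 + 2 * 2 * 6  # 36 spring-side parameters


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    y = np.asarray(y, dtype=float)
    return y + np.log(-np.expm1(-y))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _pack(params: SMSMParameters, W: np.ndarray | None) -> np.ndarray:
    vec = []
    for kp in _SINGLE_ORDER:
        p = params.singles[kp]
        vec += [_softplus_inv(p.k0), _softplus_inv(p.k1), p.l0, p.l1]
    for kp in _DOUBLE_ORDER:
        for p in params.doubles[kp]:
            vec += [_softplus_inv(p.k0), _softplus_inv(p.k1), p.l0, p.l1, p.a, p.lam]
    vec = np.array(vec, dtype=float)
    if W is not None:
        vec = np.concatenate([vec, np.asarray(W, dtype=float).ravel()])
    return vec


def _unpack(theta: np.ndarray, KH: float,
            with_W: bool) -> tuple[SMSMParameters, np.ndarray | None]:
    i = 0
    singles = {}
    for kp in _SINGLE_ORDER:
        r0, r1, l0, l1 = theta[i:i + 4]
        singles[kp] = SpringParams(float(_softplus(r0)), float(_softplus(r1)),
                                   float(l0), float(l1))
        i += 4
    doubles = {}
    for kp in _DOUBLE_ORDER:
        members = []
        for _ in range(2):
            r0, r1, l0, l1, a, lam = theta[i:i + 6]
            members.append(MuscleMember(float(_softplus(r0)), float(_softplus(r1)),
                                        float(l0), float(l1), float(a), float(lam)))
            i += 6
        doubles[kp] = tuple(members)
    W = theta[i:i + 25].reshape(5, 5).copy() if with_W else None
    params = SMSMParameters.__new__(SMSMParameters)  # skip guard during optimization
    params.singles, params.doubles, params.KH = singles, doubles, KH
    return params, W


def initial_parameters(rng: np.random.Generator, KH: float = DEFAULT_KH) -> SMSMParameters:
    """Neutral-pose-preserving initialization (l0 = 0, unit geometry)."""
    def spring():
        return SpringParams(10.0, 10.0, 0.0, float(rng.normal(0.0, 0.1)))

    singles = {kp: spring() for kp in SINGLE_SYSTEMS}
    doubles = {}
    for kp in DOUBLE_SYSTEMS:
        doubles[kp] = tuple(
            MuscleMember(10.0, 10.0, 0.0, float(rng.normal(0.0, 0.1)), 1.0, 1.0)
            for _ in range(2)
        )
    return SMSMParameters(singles=singles, doubles=doubles, KH=KH)


# ---------------------------------------------------------------------------
# loss and analytic gradient
# ---------------------------------------------------------------------------

def _forward_systems(theta, KH, U):
    """Per-system displacements plus intermediates needed for the backward pass."""
    T = U.shape[1]
    D = np.empty((5, T))
    cache = []
    i = 0
    for kp in _SINGLE_ORDER:
        r0, r1, l0, l1 = theta[i:i + 4]
        k0, k1 = _softplus(r0), _softplus(r1)
        u = U[_MUSCLE_IDX[SINGLE_SYSTEMS[kp]]]
        g = k0 + k1 * u
        h = l0 + l1 * u
        den = KH + g
        D[KEYPOINTS.index(kp)] = g * h / den
        cache.append(("single", kp, i, u, g, h, den, (r0, r1)))
        i += 4
    for kp in _DOUBLE_ORDER:
        base = i
        us, gs, hs, aa, ll, rr = [], [], [], [], [], []
        m1, m2 = DOUBLE_SYSTEMS[kp]
        for j, mus in enumerate((m1, m2)):
            r0, r1, l0, l1, a, lam = theta[i:i + 6]
            k0, k1 = _softplus(r0), _softplus(r1)
            u = U[_MUSCLE_IDX[mus]]
            us.append(u)
            gs.append(k0 + k1 * u)
            hs.append(l0 + l1 * u)
            aa.append(a)
            ll.append(lam)
            rr.append((r0, r1))
            i += 6
        num = aa[0] * gs[0] * hs[0] + aa[1] * gs[1] * hs[1]
        den = KH + aa[0] * ll[0] * gs[0] + aa[1] * ll[1] * gs[1]
        D[KEYPOINTS.index(kp)] = num / den
        cache.append(("double", kp, base, us, gs, hs, aa, ll, num, den, rr))
    return D, cache


def _loss_and_grad(theta, U, Y, KH, fit_W, penalty_weight=1e3):
    """MSE (+ denominator-positivity penalty) and its gradient in theta."""
    n_kp, T = Y.shape
    D, cache = _forward_systems(theta, KH, U)
    if fit_W:
        W = theta[_N_SPRING:].reshape(5, 5)
        P = W @ D
    else:
        W = None
        P = D
    R = P - Y
    loss = float(np.mean(R * R))
    G = (2.0 / (n_kp * T)) * R          # dL/dP
    GD = W.T @ G if fit_W else G        # dL/dD
    grad = np.zeros_like(theta)
    if fit_W:
        grad[_N_SPRING:] = (G @ D.T).ravel()

    floor = _DEN_FLOOR_FRAC * KH
    for entry in cache:
        if entry[0] == "single":
            _, kp, i, u, g, h, den, (r0, r1) = entry
            gd = GD[KEYPOINTS.index(kp)]
            viol = np.maximum(floor - den, 0.0)
            pen_d = -2.0 * penalty_weight * viol / T   # d(pen)/d(den)
            loss += penalty_weight * float(np.mean(viol * viol))
            common = h * KH / (den * den)
            dk0 = float(np.sum(gd * common) + np.sum(pen_d))
            dk1 = float(np.sum(gd * common * u) + np.sum(pen_d * u))
            grad[i + 0] = dk0 * _sigmoid(r0)
            grad[i + 1] = dk1 * _sigmoid(r1)
            grad[i + 2] = float(np.sum(gd * g / den))
            grad[i + 3] = float(np.sum(gd * g * u / den))
        else:
            _, kp, base, us, gs, hs, aa, ll, num, den, rr = entry
            gd = GD[KEYPOINTS.index(kp)]
            viol = np.maximum(floor - den, 0.0)
            pen_d = -2.0 * penalty_weight * viol / T
            loss += penalty_weight * float(np.mean(viol * viol))
            den2 = den * den
            for j in range(2):
                i = base + 6 * j
                u, g, h, a, lam = us[j], gs[j], hs[j], aa[j], ll[j]
                r0, r1 = rr[j]
                # d(dl)/dk = a*(h*den - num*lam)/den^2 ; d(den)/dk = a*lam
                dk_common = a * (h * den - num * lam) / den2
                dk0 = float(np.sum(gd * dk_common) + np.sum(pen_d) * a * lam)
                dk1 = float(np.sum(gd * dk_common * u) + np.sum(pen_d * u) * a * lam)
                grad[i + 0] = dk0 * _sigmoid(r0)
                grad[i + 1] = dk1 * _sigmoid(r1)
                grad[i + 2] = float(np.sum(gd * a * g / den))
                grad[i + 3] = float(np.sum(gd * a * g * u / den))
                grad[i + 4] = float(np.sum(gd * (g * h * den - num * lam * g) / den2)
                                    + np.sum(pen_d * lam * g))
                grad[i + 5] = float(np.sum(gd * (-num * a * g) / den2)
                                    + np.sum(pen_d * a * g))
    return loss, grad


def _adam(loss_grad, theta0, epochs, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
    theta = theta0.copy()
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    curve = np.empty(epochs)
    for t in range(1, epochs + 1):
        loss, g = loss_grad(theta)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {t}")
        curve[t - 1] = loss
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        mhat = m / (1 - beta1 ** t)
        vhat = v / (1 - beta2 ** t)
        theta = theta - lr * mhat / (np.sqrt(vhat) + eps)
    return theta, curve


# ---------------------------------------------------------------------------
# model fitting with trial-level cross-validation
# ---------------------------------------------------------------------------

MODEL_KINDS = ("SMSM", "LRM", "SMSM-LRM")


@dataclass
class FitResult:
    """Best-of-folds fitted model for one participant."""

    model_kind: str
    params: SMSMParameters | None = None
    W_lrm: np.ndarray | None = None
    W_hybrid: np.ndarray | None = None
    fold_val_losses: list[float] = field(default_factory=list)
    selected_fold: int = 0
    loss_curve: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predict(self, U: np.ndarray) -> np.ndarray:
        if self.model_kind == "LRM":
            return lrm_predict(self.W_lrm, U)
        if self.model_kind == "SMSM":
            return smsm_forward(self.params, U)
        return hybrid_predict(self.params, self.W_hybrid, U)


def fit_lrm_closed_form(U: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Exact least-squares weights: minimizes ||W U - Y||_F over W (5x7)."""
    W_t, *_ = np.linalg.lstsq(U.T, Y.T, rcond=None)
    return W_t.T


def fit_model(model_kind: str, U_trials: list[np.ndarray], Y_trials: list[np.ndarray],
              *, epochs: int = 18000, folds: int = 5, seed: int = 0,
              lr: float = 1e-3, KH: float = DEFAULT_KH,
              lrm_method: str = "closed_form") -> FitResult:
    """Fit one displacement model on per-trial (7xT, 5xT) training pairs.

    Trials are split into ``folds`` cross-validation folds; each fold's model
    is trained on the remaining folds and scored on the held-out fold, and
    the model with the lowest validation MSE is returned.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    n_trials = len(U_trials)
    if n_trials != len(Y_trials) or n_trials == 0:
        raise ValueError("need matching non-empty U and Y trial lists")
    if n_trials < folds:
        raise ValueError(f"{n_trials} trials cannot be split into {folds} folds")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_trials)
    fold_ids = [order[f::folds] for f in range(folds)]

    fold_models: list[FitResult] = []
    fold_losses: list[float] = []
    for f, val_idx in enumerate(fold_ids):
        val_set = set(int(i) for i in val_idx)
        tr_idx = [i for i in range(n_trials) if i not in val_set]
        U_tr = np.concatenate([U_trials[i] for i in tr_idx], axis=1)
        Y_tr = np.concatenate([Y_trials[i] for i in tr_idx], axis=1)
        U_val = np.concatenate([U_trials[i] for i in sorted(val_set)], axis=1)
        Y_val = np.concatenate([Y_trials[i] for i in sorted(val_set)], axis=1)

        if model_kind == "LRM" and lrm_method == "closed_form":
            W = fit_lrm_closed_form(U_tr, Y_tr)
            curve = np.array([float(np.mean((W @ U_tr - Y_tr) ** 2))])
            res = FitResult("LRM", W_lrm=W, loss_curve=curve)
        elif model_kind == "LRM":
            theta0 = 0.01 * rng.standard_normal(5 * 7)

            def lg(th):
                W = th.reshape(5, 7)
                Rm = W @ U_tr - Y_tr
                loss = float(np.mean(Rm * Rm))
                return loss, ((2.0 / Rm.size) * Rm @ U_tr.T).ravel()

            theta, curve = _adam(lg, theta0, epochs, lr=lr)
            res = FitResult("LRM", W_lrm=theta.reshape(5, 7), loss_curve=curve)
        else:
            fit_W = model_kind == "SMSM-LRM"
            p0 = initial_parameters(rng, KH=KH)
            W0 = np.eye(5) + 0.01 * rng.standard_normal((5, 5)) if fit_W else None
            theta0 = _pack(p0, W0)
            theta, curve = _adam(
                lambda th: _loss_and_grad(th, U_tr, Y_tr, KH, fit_W),
                theta0, epochs, lr=lr)
            params, W = _unpack(theta, KH, fit_W)
            res = FitResult(model_kind, params=params,
                            W_hybrid=W, loss_curve=curve)

        fold_models.append(res)
        fold_losses.append(float(np.mean((res.predict(U_val) - Y_val) ** 2)))

    selected = int(np.argmin(fold_losses))
    best = fold_models[selected]
    best.fold_val_losses = fold_losses
    best.selected_fold = selected
    return best


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def regression_metrics(Y_true: np.ndarray, Y_pred: np.ndarray) -> dict:
    """Per-keypoint R^2 (0-100 scale) and range-normalized RMSE, plus means."""
    Y_true = np.asarray(Y_true, dtype=float)
    Y_pred = np.asarray(Y_pred, dtype=float)
    if Y_true.shape != Y_pred.shape:
        raise ValueError("shape mismatch between truth and prediction")
    rng_ = Y_true.max(axis=1) - Y_true.min(axis=1)
    if np.any(rng_ <= 0):
        raise ValueError("zero range in true data; NRMSE undefined")
    sse = np.sum((Y_true - Y_pred) ** 2, axis=1)
    sst = np.sum((Y_true - Y_true.mean(axis=1, keepdims=True)) ** 2, axis=1)
    r2 = 100.0 * (1.0 - sse / sst)
    rmse = np.sqrt(np.mean((Y_true - Y_pred) ** 2, axis=1))
    nrmse = rmse / rng_
    return {
        "r2_per_keypoint": r2,
        "nrmse_per_keypoint": nrmse,
        "mean_r2": float(np.mean(r2)),
        "mean_nrmse": float(np.mean(nrmse)),
    }


@dataclass
class ModelComparison:
    f_statistic: float
    p_value: float
    tukey_p: dict[tuple[str, str], float]


def compare_models(samples: dict[str, np.ndarray]) -> ModelComparison:
    """One-way ANOVA across model groups followed by Tukey's HSD post hoc."""
    names = list(samples)
    groups = [np.asarray(samples[n], dtype=float) for n in names]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 models with >= 2 samples each")
    f, p = stats.f_oneway(*groups)
    hsd = stats.tukey_hsd(*groups)
    tukey = {}
    for i, j in itertools.combinations(range(len(names)), 2):
        tukey[(names[i], names[j])] = float(hsd.pvalue[i, j])
    return ModelComparison(float(f), float(p), tukey)
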