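"""Deep belief network regressor, implemented from scratch.

The model is a stack of restricted Boltzmann machines (RBMs) pre-trained
greedily by contrastive divergence, then unrolled into a feed-forward network
with logistic-sigmoid hidden layers and a linear scalar output, fine-tuned by
backpropagation against the mean-squared error.  Default hidden sizes are
12, 24 and 36 neurons.

Conventions:

* inputs (and, by default, labels) are min-max normalized to [0, 1] before
  training; the stored normalization parameters are reused at prediction and
  the label normalization inverted, so predictions come back in μg/m³;
* visible units are treated as real-valued in [0, 1] and CD uses mean-field
  (probability) propagation, making the update deterministic; a stochastic
  binary-sampling mode is available behind ``sample_states``;
* one reconstruction step (CD-1) by default; chain length configurable;
* fine-tuning stops when the normalized MSE reaches ``error_tolerance`` or
  after ``max_iterations`` — whichever comes first;
* every random draw flows from the seed in the training config, so the whole
  train → predict path is bit-reproducible.
"""

from __future__ import annotations

import base64
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

logger = logging.getLogger(__name__)


def logsig(x: np.ndarray) -> np.ndarray:
    """Logistic sigmoid 1/(1+exp(−x)), numerically stable on both tails."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# normalization

@dataclass
class NormalizationParams:
    """Per-column min/max for features and the label."""

    feat_min: np.ndarray
    feat_max: np.ndarray
    label_min: float = 0.0
    label_max: float = 1.0
    feature_names: list[str] = field(default_factory=list)

    def apply(self, x: np.ndarray) -> np.ndarray:
        rng = self.feat_max - self.feat_min
        out = np.empty_like(np.asarray(x, float))
        const = rng == 0
        out[:, ~const] = (x[:, ~const] - self.feat_min[~const]) / rng[~const]
        out[:, const] = 0.5
        return out

    def apply_label(self, y: np.ndarray) -> np.ndarray:
        rng = self.label_max - self.label_min
        if rng == 0:
            return np.full_like(np.asarray(y, float), 0.5)
        return (y - self.label_min) / rng

    def invert_label(self, y: np.ndarray) -> np.ndarray:
        return y * (self.label_max - self.label_min) + self.label_min


def minmax_fit(x: np.ndarray, y: np.ndarray | None = None,
               feature_names: list[str] | None = None) -> NormalizationParams:
    """Fit min-max normalization; constant columns map to 0.5 with a warning."""
    x = np.asarray(x, float)
    if x.ndim != 2 or len(x) < 2:
        raise ValueError("need a 2-D matrix with at least two samples")
    if not np.all(np.isfinite(x)):
        bad = np.where(~np.isfinite(x).all(axis=0))[0]
        names = ([feature_names[i] for i in bad] if feature_names
                 else bad.tolist())
        raise ValueError(f"non-finite values in feature column(s) {names}")
    lo, hi = x.min(axis=0), x.max(axis=0)
    const = np.where(lo == hi)[0]
    if len(const):
        names = [feature_names[i] for i in const] if feature_names else const.tolist()
        warnings.warn(f"constant feature column(s) {names} mapped to 0.5")
    p = NormalizationParams(lo, hi, feature_names=list(feature_names or []))
    if y is not None:
        y = np.asarray(y, float)
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in labels")
        p.label_min, p.label_max = float(y.min()), float(y.max())
    return p


def minmax_fit_apply(x: np.ndarray, y: np.ndarray | None = None,
                     feature_names: list[str] | None = None):
    """Fit and apply in one step; returns (x_norm[, y_norm], params)."""
    p = minmax_fit(x, y, feature_names)
    xn = p.apply(np.asarray(x, float))
    if y is None:
        return xn, p
    return xn, p.apply_label(np.asarray(y, float)), p


# ---------------------------------------------------------------------------
# RBM

@dataclass
class RBMParams:
    """One RBM layer: weights W (visible m × hidden n), visible bias b (m),
    hidden bias c (n)."""

    W: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, float)
        self.b = np.asarray(self.b, float).ravel()
        self.c = np.asarray(self.c, float).ravel()
        m, n = self.W.shape
        if self.b.shape != (m,) or self.c.shape != (n,):
            raise ValueError("inconsistent RBM parameter shapes")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.b))
                and np.all(np.isfinite(self.c))):
            raise ValueError("non-finite RBM parameters")

    def copy(self) -> "RBMParams":
        return RBMParams(self.W.copy(), self.b.copy(), self.c.copy())


def hidden_activation(v: np.ndarray, rbm: RBMParams) -> np.ndarray:
    """p(h_j = 1 | v) = logsig(Σ_i w_ij v_i + c_j); accepts a vector or batch."""
    v = np.asarray(v, float)
    single = v.ndim == 1
    v2 = np.atleast_2d(v)
    if v2.shape[1] != rbm.W.shape[0]:
        raise ValueError(f"visible size {v2.shape[1]} != m = {rbm.W.shape[0]}")
    p = logsig(v2 @ rbm.W + rbm.c)
    return p[0] if single else p


def visible_reconstruction(h: np.ndarray, rbm: RBMParams) -> np.ndarray:
    """p(v_i = 1 | h) = logsig(Σ_j w_ij h_j + b_i)."""
    h = np.asarray(h, float)
    single = h.ndim == 1
    h2 = np.atleast_2d(h)
    if h2.shape[1] != rbm.W.shape[1]:
        raise ValueError(f"hidden size {h2.shape[1]} != n = {rbm.W.shape[1]}")
    p = logsig(h2 @ rbm.W.T + rbm.b)
    return p[0] if single else p


def cd_update(batch: np.ndarray, rbm: RBMParams, lam: float,
              n_steps: int = 1, sample_states: bool = False,
              rng: np.random.Generator | None = None) -> RBMParams:
    """One contrastive-divergence parameter update on a batch.

    Data-phase statistics use p(h|v_data); the reconstruction chain runs
    ``n_steps`` alternations (CD-1 by default) with mean-field probabilities,
    or with Bernoulli-sampled hidden states when ``sample_states`` is set.
    Updates are averaged over the batch:

        w_ij += λ ( <p(h_j|v) v_i>_data − <p(h_j|v') v'_i>_recon )
        b_i  += λ ( <v_i>_data − <v'_i>_recon )
        c_j  += λ ( <p(h_j|v)>_data − <p(h_j|v')>_recon )
    """
    v0 = np.atleast_2d(np.asarray(batch, float))
    if len(v0) == 0:
        raise ValueError("empty batch")
    if v0.min() < 0 or v0.max() > 1:
        raise ValueError("visible values outside [0, 1]; normalize first")
    if sample_states and rng is None:
        raise ValueError("sampling mode requires an rng")
    ph0 = hidden_activation(v0, rbm)
    h = (rng.random(ph0.shape) < ph0).astype(float) if sample_states else ph0
    vk, phk = v0, ph0
    for _ in range(n_steps):
        vk = visible_reconstruction(h, rbm)
        phk = hidden_activation(vk, rbm)
        h = (rng.random(phk.shape) < phk).astype(float) if sample_states else phk
    bsz = len(v0)
    new = rbm.copy()
    new.W += lam * (v0.T @ ph0 - vk.T @ phk) / bsz
    new.b += lam * (v0 - vk).mean(axis=0)
    new.c += lam * (ph0 - phk).mean(axis=0)
    return new


cd1_update = cd_update  # CD-1 is the default chain length


# ---------------------------------------------------------------------------
# training configuration

@dataclass
class TrainConfig:
    """Knobs of the pre-training and fine-tuning stages.

    All values are stored with the fitted model.  Rates are in normalized
    units; ``error_tolerance`` applies to the normalized-scale MSE.
    """

    hidden_sizes: tuple[int, ...] = (12, 24, 36)
    cd_learning_rate: float = 0.1
    cd_epochs: int = 50
    cd_steps: int = 1
    sample_states: bool = False
    fine_tune_method: str = "levenberg_marquardt"
    bp_learning_rate: float = 0.1
    max_iterations: int = 500
    error_tolerance: float = 1e-4
    batch_size: int = 64
    init_scale: float = 0.6
    normalize_labels: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cd_learning_rate <= 0 or self.bp_learning_rate <= 0:
            raise ValueError("learning rates must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.fine_tune_method not in ("levenberg_marquardt", "gradient"):
            raise ValueError(f"unknown fine-tune method {self.fine_tune_method!r}")


def _init_rbm(m: int, n: int, rng: np.random.Generator, scale: float) -> RBMParams:
    return RBMParams(rng.normal(0.0, scale, (m, n)), np.zeros(m), np.zeros(n))


def pretrain_stack(x: np.ndarray, cfg: TrainConfig) -> tuple[list[RBMParams], list[list[float]]]:
    """Greedy layer-wise CD pre-training.

    RBM 1 is trained on the normalized inputs; RBM k on the hidden
    activations of RBM k−1.  Returns the stack and the per-layer, per-epoch
    mean reconstruction errors (monitored; decreasing in the long-run trend).
    """
    x = np.atleast_2d(np.asarray(x, float))
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    stack: list[RBMParams] = []
    logs: list[list[float]] = []
    data = x
    for size in cfg.hidden_sizes:
        rbm = _init_rbm(data.shape[1], size, rng, cfg.init_scale)
        errs: list[float] = []
        for _ in range(cfg.cd_epochs):
            order = rng.permutation(len(data))
            for s in range(0, len(data), cfg.batch_size):
                batch = data[order[s:s + cfg.batch_size]]
                rbm = cd_update(batch, rbm, cfg.cd_learning_rate,
                                n_steps=cfg.cd_steps,
                                sample_states=cfg.sample_states, rng=rng)
            recon = visible_reconstruction(hidden_activation(data, rbm), rbm)
            errs.append(float(np.mean((data - recon) ** 2)))
        stack.append(rbm)
        logs.append(errs)
        data = hidden_activation(data, rbm)
    return stack, logs


# ---------------------------------------------------------------------------
# feed-forward network (unrolled DBN) and fine-tuning

def _forward(x: np.ndarray, Ws, bs, w_out, b_out):
    """Forward pass; returns per-layer activations and the scalar output."""
    acts = [x]
    a = x
    for W, b in zip(Ws, bs):
        a = logsig(a @ W + b)
        acts.append(a)
    return acts, a @ w_out + b_out


def _flatten(Ws, bs, w_out, b_out) -> np.ndarray:
    parts = []
    for W, b in zip(Ws, bs):
        parts += [W.ravel(), b]
    parts += [w_out, np.array([b_out])]
    return np.concatenate(parts)


def _unflatten(theta: np.ndarray, shapes):
    Ws, bs, pos = [], [], 0
    for m, n in shapes:
        Ws.append(theta[pos:pos + m * n].reshape(m, n)); pos += m * n
        bs.append(theta[pos:pos + n]); pos += n
    n_last = shapes[-1][1]
    w_out = theta[pos:pos + n_last]; pos += n_last
    b_out = float(theta[pos])
    return Ws, bs, w_out, b_out


def _jacobian(x, Ws, bs, w_out, b_out):
    """Jacobian of the scalar network output w.r.t. all parameters, (n, p)."""
    acts, _ = _forward(x, Ws, bs, w_out, b_out)
    n = len(x)
    # backprop sensitivities of the output w.r.t. each layer's pre-activation
    gs = [None] * len(Ws)
    g = w_out[None, :] * acts[-1] * (1 - acts[-1])
    gs[-1] = g
    for k in range(len(Ws) - 2, -1, -1):
        g = (g @ Ws[k + 1].T) * acts[k + 1] * (1 - acts[k + 1])
        gs[k] = g
    blocks = []
    for k in range(len(Ws)):
        blocks.append((acts[k][:, :, None] * gs[k][:, None, :]).reshape(n, -1))
        blocks.append(gs[k])
    blocks.append(acts[-1])
    blocks.append(np.ones((n, 1)))
    return np.concatenate(blocks, axis=1)


def network_gradient(x, y, Ws, bs, w_out, b_out):
    """Gradient of E = (1/n) Σ (y − ŷ)² w.r.t. the flattened parameters."""
    J = _jacobian(x, Ws, bs, w_out, b_out)
    _, yhat = _forward(x, Ws, bs, w_out, b_out)
    r = y - yhat
    return (-2.0 / len(x)) * (J.T @ r)


@dataclass
class DBNModel:
    """Fine-tuned DBN regressor: logsig hidden layers + linear scalar output."""

    Ws: list[np.ndarray]
    bs: list[np.ndarray]
    w_out: np.ndarray
    b_out: float
    norm: NormalizationParams
    config: TrainConfig
    pretrain_log: list[list[float]] = field(default_factory=list)
    finetune_log: list[float] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return self.norm.feature_names

    def predict(self, x: np.ndarray,
                feature_names: list[str] | None = None) -> np.ndarray:
        """Predict PM2.5 (μg/m³) for raw (unnormalized) feature rows.

        If ``feature_names`` is given it must match the training layout.
        Features outside the training min/max extrapolate (their normalized
        value leaves [0, 1]); this is permitted and logged.
        """
        if feature_names is not None and self.feature_names:
            if list(feature_names) != self.feature_names:
                raise ValueError(
                    f"feature mismatch: model expects {self.feature_names}, "
                    f"got {list(feature_names)}")
        x = np.atleast_2d(np.asarray(x, float))
        if x.shape[1] != self.Ws[0].shape[0]:
            raise ValueError(f"expected {self.Ws[0].shape[0]} features, "
                             f"got {x.shape[1]}")
        xn = self.norm.apply(x)
        if xn.min() < 0 or xn.max() > 1:
            logger.info("inputs outside the training range; extrapolating")
        _, yhat = _forward(xn, self.Ws, self.bs, self.w_out, self.b_out)
        if self.config.normalize_labels:
            yhat = self.norm.invert_label(yhat)
        return yhat

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        """Single-file JSON artifact with base64 little-endian float64 arrays
        (bit-exact and byte-deterministic)."""
        def enc(a):
            a = np.ascontiguousarray(np.asarray(a, "<f8"))
            return {"shape": list(a.shape),
                    "data": base64.b64encode(a.tobytes()).decode()}
        doc = {
            "format": "pm-gridsense-dbn-1",
            "layers": [{"W": enc(W), "b": enc(b)}
                       for W, b in zip(self.Ws, self.bs)],
            "w_out": enc(self.w_out),
            "b_out": self.b_out,
            "norm": {"feat_min": enc(self.norm.feat_min),
                     "feat_max": enc(self.norm.feat_max),
                     "label_min": self.norm.label_min,
                     "label_max": self.norm.label_max,
                     "feature_names": self.norm.feature_names},
            "config": {**asdict(self.config),
                       "hidden_sizes": list(self.config.hidden_sizes)},
            "pretrain_log": self.pretrain_log,
            "finetune_log": self.finetune_log,
        }
        with open(path, "w") as f:
            json.dump(doc, f, sort_keys=True)

    @classmethod
    def load(cls, path) -> "DBNModel":
        with open(path) as f:
            doc = json.load(f)
        def dec(d):
            return np.frombuffer(base64.b64decode(d["data"]),
                                 dtype="<f8").reshape(d["shape"]).copy()
        cfg = dict(doc["config"])
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        norm = NormalizationParams(dec(doc["norm"]["feat_min"]),
                                   dec(doc["norm"]["feat_max"]),
                                   doc["norm"]["label_min"],
                                   doc["norm"]["label_max"],
                                   doc["norm"]["feature_names"])
        return cls([dec(l["W"]) for l in doc["layers"]],
                   [dec(l["b"]).ravel() for l in doc["layers"]],
                   dec(doc["w_out"]).ravel(), float(doc["b_out"]),
                   norm, TrainConfig(**cfg),
                   doc.get("pretrain_log", []), doc.get("finetune_log", []))


def fine_tune(stack: list[RBMParams], x: np.ndarray, y: np.ndarray,
              cfg: TrainConfig, norm: NormalizationParams,
              pretrain_log=None) -> DBNModel:
    """Backpropagation fine-tuning of the unrolled stack against the MSE.

    ``gradient`` mode is the literal steepest-descent update w ← w − η ∇E(w);
    ``levenberg_marquardt`` solves (JᵀJ + μI) δ = Jᵀe with μ adapted ×10/÷10
    on failure/success.  Stops at E ≤ error_tolerance or max_iterations.
    The returned model never has a higher training error than the initial one.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.asarray(y, float).ravel()
    if len(x) < 10:
        raise ValueError("need at least 10 labeled samples to fine-tune")
    for k, rbm in enumerate(stack[1:], 1):
        if rbm.W.shape[0] != stack[k - 1].W.shape[1]:
            raise ValueError("stack layer dimensions do not chain")
    Ws = [r.W.copy() for r in stack]
    bs = [r.c.copy() for r in stack]  # hidden biases become layer biases
    # initialize the linear readout by least squares on the top activations:
    # starting from near-zero output weights stalls backpropagation, because
    # every hidden-layer gradient scales with them
    acts, _ = _forward(x, Ws, bs, np.zeros(stack[-1].W.shape[1]), 0.0)
    design = np.column_stack([acts[-1], np.ones(len(x))])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    w_out, b_out = coef[:-1], float(coef[-1])
    shapes = [W.shape for W in Ws]
    theta = _flatten(Ws, bs, w_out, b_out)

    def error(th):
        Ws_, bs_, wo_, bo_ = _unflatten(th, shapes)
        _, yhat = _forward(x, Ws_, bs_, wo_, bo_)
        return float(np.mean((y - yhat) ** 2))

    log = [error(theta)]
    if cfg.fine_tune_method == "gradient":
        for _ in range(cfg.max_iterations):
            if log[-1] <= cfg.error_tolerance:
                break
            Ws_, bs_, wo_, bo_ = _unflatten(theta, shapes)
            theta = theta - cfg.bp_learning_rate * network_gradient(
                x, y, Ws_, bs_, wo_, bo_)
            e = error(theta)
            if not np.isfinite(e):
                raise RuntimeError(
                    f"fine-tuning diverged (E={e}) after {len(log)} steps; "
                    f"reduce bp_learning_rate")
            log.append(e)
    else:  # Levenberg-Marquardt with explicit Jacobian
        from scipy.linalg import blas as _blas, cho_factor, cho_solve

        mu = 1e-3
        e_cur = log[-1]
        it = 0
        eye = np.eye(len(theta))
        while it < cfg.max_iterations and e_cur > cfg.error_tolerance:
            it += 1
            Ws_, bs_, wo_, bo_ = _unflatten(theta, shapes)
            J = _jacobian(x, Ws_, bs_, wo_, bo_)
            _, yhat = _forward(x, Ws_, bs_, wo_, bo_)
            r = y - yhat
            # JᵀJ is symmetric: rank-k update does half the flops of a GEMM
            A = _blas.dsyrk(1.0, J, trans=1)
            A = A + np.triu(A, 1).T
            g = J.T @ r
            improved = False
            for _ in range(20):
                try:
                    delta = cho_solve(cho_factor(A + mu * eye, lower=False), g)
                except np.linalg.LinAlgError:
                    mu *= 10.0
                    continue
                e_new = error(theta + delta)
                if np.isfinite(e_new) and e_new < e_cur:
                    theta = theta + delta
                    e_cur = e_new
                    mu = max(mu / 10.0, 1e-12)
                    improved = True
                    break
                mu *= 10.0
            log.append(e_cur)
            if not improved:
                break  # converged: no damped step improves the error
    if not np.isfinite(log[-1]):
        raise RuntimeError("fine-tuning produced a non-finite error")
    Ws, bs, w_out, b_out = _unflatten(theta, shapes)
    return DBNModel(Ws, bs, w_out, b_out, norm, cfg,
                    pretrain_log or [], log)


def train_dbn(x: np.ndarray, y: np.ndarray, cfg: TrainConfig | None = None,
              feature_names: list[str] | None = None) -> DBNModel:
    """Full pipeline: min-max normalize, CD pre-train, BP fine-tune."""
    cfg = cfg or TrainConfig()
    x = np.atleast_2d(np.asarray(x, float))
    y = np.asarray(y, float).ravel()
    norm = minmax_fit(x, y, feature_names)
    xn = norm.apply(x)
    yn = norm.apply_label(y) if cfg.normalize_labels else y
    stack, logs = pretrain_stack(xn, cfg)
    return fine_tune(stack, xn, yn, cfg, norm, pretrain_log=logs)
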