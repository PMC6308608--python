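"""Deep probabilistic state-space model with structured variational inference.

Generative model (a deep Markov model over LSTM embedding sequences):

    z_1 ~ N(mu_0, diag v_0)
    z_t | z_{t-1} ~ N(f_mu(z_{t-1}), diag f_var(z_{t-1}))      (transition)
    x_t | z_t     ~ N(g_mu(z_t),     diag g_var(z_t))          (emission)

with f and g small neural networks (parameters theta). The variational
posterior factorizes forward in time but conditions on future data through
a backward recurrent summarizer r_t = summary of x_{t:T}:

    q(z_t | z_{t-1}, x_{t:T}) = N(mu_phi(z_{t-1}, r_t), diag var_phi(...))

Training maximizes the evidence lower bound

    ELBO = E_q[log p(x_{1:T} | z_{1:T})] - KL(q(z_{1:T}|x) || p(z_{1:T}))

with the reconstruction term estimated by reparameterized Monte Carlo and
the per-step KL computed in closed form given the sampled z_{t-1}. The
observations are the frozen classifier's level-2 hidden-state sequences,
so the latent trajectories inherit the player/skill discrimination that the
classifier learned.

A Kalman-filter log-likelihood oracle for linear-Gaussian instances is
included as test support: on such models the ELBO can be checked against
the exact evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .lstm_core import ClassifierParams, run_stack

_VAR_FLOOR = 1e-4
_LOG2PI = float(np.log(2.0 * np.pi))


def _softplus_np(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    # inverse of log(1+e^x); y must be > 0
    return np.log(np.expm1(y))


# -- building blocks -------------------------------------------------------


class GaussianNet:
    """Maps an input vector to a diagonal Gaussian (mean, variance).

    One tanh hidden layer by default; ``hidden=None`` gives an affine mean.
    With ``const_var=True`` the variance is a free per-dimension parameter
    independent of the input, which lets the net represent an exactly
    linear-Gaussian conditional.
    """

    def __init__(self, in_dim, out_dim, hidden=32, const_var=False,
                 rng=None, prefix=""):
        rng = rng or np.random.default_rng(0)
        self.hidden = hidden
        self.const_var = const_var
        self.prefix = prefix
        d = in_dim if hidden is None else hidden
        self.params: dict[str, Tensor] = {}

        def p(name, arr):
            t = Tensor(arr, requires_grad=True)
            self.params[name] = t
            return t

        if hidden is not None:
            s = 1.0 / np.sqrt(in_dim)
            self.Wh = p("Wh", rng.uniform(-s, s, (in_dim, hidden)))
            self.bh = p("bh", np.zeros(hidden))
        s = 1.0 / np.sqrt(d)
        self.Wm = p("Wm", rng.uniform(-s, s, (d, out_dim)))
        self.bm = p("bm", np.zeros(out_dim))
        if const_var:
            self.rawv = p("rawv", np.full(out_dim, _softplus_inv(1.0)))
        else:
            self.Wv = p("Wv", rng.uniform(-s, s, (d, out_dim)))
            self.bv = p("bv", np.zeros(out_dim))

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = (x @ self.Wh + self.bh).tanh() if self.hidden is not None else x
        mean = h @ self.Wm + self.bm
        if self.const_var:
            var = self.rawv.softplus() + _VAR_FLOOR
            # broadcast handled by autodiff ops
        else:
            var = (h @ self.Wv + self.bv).softplus() + _VAR_FLOOR
        return mean, var

    def mean_var_np(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Gradient-free NumPy evaluation (used for mean propagation)."""
        h = np.tanh(x @ self.Wh.data + self.bh.data) if self.hidden is not None else x
        mean = h @ self.Wm.data + self.bm.data
        if self.const_var:
            var = np.broadcast_to(
                _softplus_np(self.rawv.data) + _VAR_FLOOR, mean.shape
            )
        else:
            var = _softplus_np(h @ self.Wv.data + self.bv.data) + _VAR_FLOOR
        return mean, var

    def set_linear(self, A: np.ndarray, b: np.ndarray, var_diag: np.ndarray):
        """Pin the net to mean = x A^T + b with constant diagonal variance."""
        if self.hidden is not None or not self.const_var:
            raise ValueError("set_linear requires hidden=None and const_var=True")
        self.Wm.data = np.asarray(A, dtype=float).T.copy()
        self.bm.data = np.asarray(b, dtype=float).copy()
        self.rawv.data = _softplus_inv(np.asarray(var_diag, dtype=float) - _VAR_FLOOR)


@dataclass
class GenerativeParams:
    """theta: initial-state prior, transition net f, emission net g."""

    latent_dim: int
    obs_dim: int
    z0_mean: Tensor
    z0_rawvar: Tensor
    transition: GaussianNet
    emission: GaussianNet

    @classmethod
    def create(cls, latent_dim, obs_dim, hidden=32, const_var=False, rng=None):
        rng = rng or np.random.default_rng(0)
        return cls(
            latent_dim=latent_dim,
            obs_dim=obs_dim,
            z0_mean=Tensor(np.zeros(latent_dim), requires_grad=True),
            z0_rawvar=Tensor(
                np.full(latent_dim, _softplus_inv(1.0)), requires_grad=True
            ),
            transition=GaussianNet(latent_dim, latent_dim, hidden, const_var,
                                   rng, "trans"),
            emission=GaussianNet(latent_dim, obs_dim, hidden, const_var,
                                 rng, "emis"),
        )

    def prior_init(self) -> tuple[Tensor, Tensor]:
        return self.z0_mean, self.z0_rawvar.softplus() + _VAR_FLOOR

    def parameters(self) -> list[tuple[str, Tensor]]:
        out = [("z0_mean", self.z0_mean), ("z0_rawvar", self.z0_rawvar)]
        out += [(f"trans.{k}", t) for k, t in self.transition.params.items()]
        out += [(f"emis.{k}", t) for k, t in self.emission.params.items()]
        return out


@dataclass
class InferenceParams:
    """phi: backward recurrent summarizer + posterior Gaussian net."""

    latent_dim: int
    obs_dim: int
    summary_dim: int
    Wr: Tensor  # (obs, R)
    Ur: Tensor  # (R, R)
    br: Tensor  # (R,)
    posterior: GaussianNet  # over concat(z_prev, r_t)

    @classmethod
    def create(cls, latent_dim, obs_dim, summary_dim=32, hidden=32, rng=None):
        rng = rng or np.random.default_rng(0)
        so = 1.0 / np.sqrt(obs_dim)
        sr = 1.0 / np.sqrt(summary_dim)
        return cls(
            latent_dim=latent_dim,
            obs_dim=obs_dim,
            summary_dim=summary_dim,
            Wr=Tensor(rng.uniform(-so, so, (obs_dim, summary_dim)), requires_grad=True),
            Ur=Tensor(rng.uniform(-sr, sr, (summary_dim, summary_dim)),
                      requires_grad=True),
            br=Tensor(np.zeros(summary_dim), requires_grad=True),
            posterior=GaussianNet(latent_dim + summary_dim, latent_dim, hidden,
                                  False, rng, "post"),
        )

    def summarize(self, X: np.ndarray) -> list[Tensor]:
        """Backward recurrence r_t over x_{t:T}; X is (B, T, D)."""
        B, T, _ = X.shape
        r = Tensor(np.zeros((B, self.summary_dim)))
        rs: list[Tensor] = [None] * T
        for t in range(T - 1, -1, -1):
            r = (Tensor(X[:, t]) @ self.Wr + r @ self.Ur + self.br).tanh()
            rs[t] = r
        return rs

    def summarize_np(self, X: np.ndarray) -> np.ndarray:
        B, T, _ = X.shape
        r = np.zeros((B, self.summary_dim))
        out = np.empty((B, T, self.summary_dim))
        for t in range(T - 1, -1, -1):
            r = np.tanh(X[:, t] @ self.Wr.data + r @ self.Ur.data + self.br.data)
            out[:, t] = r
        return out

    def parameters(self) -> list[tuple[str, Tensor]]:
        out = [("Wr", self.Wr), ("Ur", self.Ur), ("br", self.br)]
        out += [(f"post.{k}", t) for k, t in self.posterior.params.items()]
        return out


@dataclass
class LatentTrajectory:
    """Posterior-mean latent path for one stroke, the coaching artifact."""

    subject_id: str
    skill_id: str
    rep_index: int
    split: str
    z: np.ndarray  # (T, latent_dim)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("latent trajectory must be finite")


@dataclass
class ELBOReport:
    """ELBO decomposition; total = reconstruction - KL (per sequence)."""

    total: np.ndarray  # (B,)
    reconstruction: np.ndarray
    kl: np.ndarray

    @property
    def mean_total(self) -> float:
        return float(np.mean(self.total))

    @property
    def mean_reconstruction(self) -> float:
        return float(np.mean(self.reconstruction))

    @property
    def mean_kl(self) -> float:
        return float(np.mean(self.kl))


# -- closed-form pieces ----------------------------------------------------


def kl_gaussian(q_mean, q_var, p_mean, p_var) -> float:
    """KL(N(q_mean, diag q_var) || N(p_mean, diag p_var)), closed form."""
    q_mean, q_var = np.asarray(q_mean, float), np.asarray(q_var, float)
    p_mean, p_var = np.asarray(p_mean, float), np.asarray(p_var, float)
    if np.any(q_var <= 0) or np.any(p_var <= 0):
        raise ValueError("variances must be strictly positive")
    return float(
        0.5
        * np.sum(np.log(p_var) - np.log(q_var) + (q_var + (q_mean - p_mean) ** 2) / p_var - 1.0)
    )


def _kl_t(qm: Tensor, qv: Tensor, pm: Tensor, pv: Tensor) -> Tensor:
    """Per-sequence closed-form KL between diagonal Gaussians -> (B,)."""
    term = pv.log() - qv.log() + (qv + (qm - pm).square()) / pv - 1.0
    return term.sum(axis=1) * 0.5


def _gauss_logpdf(x: Tensor, mean: Tensor, var: Tensor) -> Tensor:
    """Diagonal-Gaussian log density summed over dimensions -> (B,)."""
    q = (x - mean).square() / var
    return ((var.log() + q + _LOG2PI) * (-0.5)).sum(axis=1)


# -- ELBO ------------------------------------------------------------------


def elbo(
    gen: GenerativeParams,
    inf: InferenceParams,
    X: np.ndarray,
    n_samples: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[Tensor, ELBOReport]:
    """Monte-Carlo ELBO of a batch of sequences X (B, T, D) or (T, D).

    Reconstruction is a reparameterized ``n_samples``-sample average; the
    KL term is analytic per time step conditioned on the sampled z_{t-1}.
    Returns the scalar mean-ELBO graph node (for gradients) and a report
    with per-sequence terms.
    """
    rng = rng or np.random.default_rng(0)
    X = np.asarray(X, float)
    if X.ndim == 2:
        X = X[None]
    B, T, D = X.shape
    if D != gen.obs_dim or D != inf.obs_dim:
        raise ValueError(f"obs_dim mismatch: data {D}, model {gen.obs_dim}")
    rs = inf.summarize(X)
    ones_B = Tensor(np.ones((B, 1)))
    recon_acc: Tensor | None = None
    kl_acc: Tensor | None = None
    for _s in range(n_samples):
        z_prev = ones_B @ gen.z0_mean.reshape(1, -1)
        recon_s: Tensor | None = None
        kl_s: Tensor | None = None
        for t in range(T):
            qm, qv = inf.posterior(concat([z_prev, rs[t]], axis=1))
            if t == 0:
                pm0, pv0 = gen.prior_init()
                pm = ones_B @ pm0.reshape(1, -1)
                pv = ones_B @ pv0.reshape(1, -1)
            else:
                pm, pv = gen.transition(z_prev)
            klt = _kl_t(qm, qv, pm, pv)
            eps = rng.standard_normal((B, gen.latent_dim))
            z = qm + qv.sqrt() * Tensor(eps)
            em, ev = gen.emission(z)
            rt = _gauss_logpdf(Tensor(X[:, t]), em, ev)
            recon_s = rt if recon_s is None else recon_s + rt
            kl_s = klt if kl_s is None else kl_s + klt
            z_prev = z
        recon_acc = recon_s if recon_acc is None else recon_acc + recon_s
        kl_acc = kl_s if kl_acc is None else kl_acc + kl_s
    recon = recon_acc * (1.0 / n_samples)
    kl = kl_acc * (1.0 / n_samples)
    total = recon - kl
    if not np.all(np.isfinite(total.data)):
        bad = np.nonzero(~np.isfinite(total.data))[0]
        raise FloatingPointError(f"non-finite ELBO for sequence(s) {bad.tolist()}")
    report = ELBOReport(
        total=total.data.copy(),
        reconstruction=recon.data.copy(),
        kl=kl.data.copy(),
    )
    return total.mean(), report


def elbo_given_q(
    gen: GenerativeParams,
    X: np.ndarray,
    q_means: np.ndarray,
    q_vars: np.ndarray,
    n_samples: int = 1,
    rng: np.random.Generator | None = None,
) -> ELBOReport:
    """ELBO under an explicit mean-field Gaussian q(z_t) = N(q_means[t], diag q_vars[t]).

    Test support: lets exact posteriors (e.g. from a Kalman smoother) be
    plugged in directly. X is (T, D); q_means/q_vars are (T, L).
    """
    rng = rng or np.random.default_rng(0)
    X = np.asarray(X, float)
    q_means = np.asarray(q_means, float)
    q_vars = np.asarray(q_vars, float)
    T = X.shape[0]
    L = gen.latent_dim
    pm0, pv0 = gen.prior_init()
    recon = 0.0
    kl = 0.0
    z_samples = q_means[None] + np.sqrt(q_vars)[None] * rng.standard_normal(
        (n_samples, T, L)
    )
    for t in range(T):
        z_t = z_samples[:, t]  # (S, L)
        em, ev = gen.emission.mean_var_np(z_t)
        recon += float(
            np.mean(
                np.sum(-0.5 * (np.log(ev) + (X[t] - em) ** 2 / ev + _LOG2PI), axis=1)
            )
        )
        if t == 0:
            kl += kl_gaussian(q_means[0], q_vars[0], pm0.data, pv0.data)
        else:
            pm, pv = gen.transition.mean_var_np(z_samples[:, t - 1])
            kl += float(
                np.mean(
                    [
                        kl_gaussian(q_means[t], q_vars[t], pm[s], pv[s])
                        for s in range(n_samples)
                    ]
                )
            )
    total = recon - kl
    return ELBOReport(
        total=np.array([total]),
        reconstruction=np.array([recon]),
        kl=np.array([kl]),
    )


# -- embeddings ------------------------------------------------------------


def embed_sequence(classifier: ClassifierParams, stroke: np.ndarray) -> np.ndarray:
    """Level-2 hidden-state sequence of the frozen classifier -> (T, obs_dim).

    For the bidirectional model this is the forward || backward
    concatenation aligned to original time; entries lie in (-1, 1).
    """
    out = run_stack(classifier, np.asarray(stroke, float))
    return out["h2"]


def embed_dataset(classifier: ClassifierParams, dataset) -> np.ndarray:
    """Embeddings for every stroke -> (N, T, obs_dim), dataset order."""
    X, _ = dataset.to_arrays()
    return run_stack(classifier, X)["h2"]


# -- training --------------------------------------------------------------


@dataclass
class DMMTrainConfig:
    """Stochastic gradient ascent on the dataset-mean ELBO (Adam)."""

    epochs: int = 500
    learning_rate: float = 1e-2
    seed: int = 0
    n_samples: int = 1
    hidden: int = 32
    summary_dim: int = 32
    const_var: bool = False
    net_hidden: int | None = 32  # None -> affine transition/emission


def train_dmm(
    X: np.ndarray,
    latent_dim: int,
    cfg: DMMTrainConfig | None = None,
) -> tuple[GenerativeParams, InferenceParams, list[float]]:
    """Fit theta and phi by maximizing the mean ELBO over sequences X (N, T, D).

    Full-batch Adam with reparameterized single-sample gradients by
    default; deterministic given ``cfg.seed``. Returns the fitted
    parameters and the per-epoch mean-ELBO curve.
    """
    cfg = cfg or DMMTrainConfig()
    X = np.asarray(X, float)
    if X.ndim == 2:
        X = X[None]
    _, _, D = X.shape
    init_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 4)))
    gen = GenerativeParams.create(
        latent_dim, D, hidden=cfg.net_hidden, const_var=cfg.const_var, rng=init_rng
    )
    inf = InferenceParams.create(
        latent_dim, D, summary_dim=cfg.summary_dim, hidden=cfg.hidden, rng=init_rng
    )
    noise_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 5)))
    params = [t for _, t in gen.parameters() + inf.parameters()]
    m = [np.zeros_like(p.data) for p in params]
    v = [np.zeros_like(p.data) for p in params]
    b1, b2, eps = 0.9, 0.999, 1e-8
    curve: list[float] = []
    for step in range(1, cfg.epochs + 1):
        for p in params:
            p.grad = None
        mean_elbo, report = elbo(gen, inf, X, n_samples=cfg.n_samples, rng=noise_rng)
        loss = -mean_elbo
        loss.backward()
        if not np.isfinite(loss.data):
            raise FloatingPointError("DMM training diverged (ELBO not finite)")
        lr_t = cfg.learning_rate * np.sqrt(1 - b2**step) / (1 - b1**step)
        for k, p in enumerate(params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            m[k] = b1 * m[k] + (1 - b1) * g
            v[k] = b2 * v[k] + (1 - b2) * g**2
            p.data = p.data - lr_t * m[k] / (np.sqrt(v[k]) + eps)
        curve.append(report.mean_total)
    return gen, inf, curve


def infer_trajectory(
    gen: GenerativeParams, inf: InferenceParams, embedding: np.ndarray
) -> np.ndarray:
    """Deterministic posterior-mean path: z_t = mu_phi(z_{t-1}, r_t) -> (T, L).

    Mean propagation with z_0 = prior mean; no sampling.
    """
    X = np.asarray(embedding, float)[None]  # (1, T, D)
    rs = inf.summarize_np(X)[0]  # (T, R)
    T = X.shape[1]
    z = gen.z0_mean.data.copy()
    out = np.empty((T, gen.latent_dim))
    for t in range(T):
        qm, _ = inf.posterior.mean_var_np(
            np.concatenate([z, rs[t]])[None]
        )
        z = qm[0]
        out[t] = z
    return out


def infer_trajectories(
    gen: GenerativeParams,
    inf: InferenceParams,
    classifier: ClassifierParams,
    dataset,
) -> list[LatentTrajectory]:
    """Latent trajectories for every stroke in a (scaled) dataset."""
    emb = embed_dataset(classifier, dataset)
    out = []
    for s, e in zip(dataset.strokes, emb):
        out.append(
            LatentTrajectory(
                s.subject_id, s.skill_id, s.rep_index, s.split,
                infer_trajectory(gen, inf, e),
            )
        )
    return out


# -- Kalman oracle (test support) ------------------------------------------


def kalman_loglik_oracle(
    A: np.ndarray,
    C: np.ndarray,
    Q: np.ndarray,
    R: np.ndarray,
    m0: np.ndarray,
    S0: np.ndarray,
    X: np.ndarray,
) -> float:
    """Exact log p(x_{1:T}) of a linear-Gaussian state-space model.

    z_1 ~ N(m0, S0); z_t = A z_{t-1} + w, w ~ N(0, Q); x_t = C z_t + v,
    v ~ N(0, R). Computed by the Kalman-filter prediction-error
    decomposition. Raises on a singular innovation covariance.
    """
    A, C, Q, R = (np.atleast_2d(np.asarray(a, float)) for a in (A, C, Q, R))
    m0 = np.atleast_1d(np.asarray(m0, float))
    S0 = np.atleast_2d(np.asarray(S0, float))
    X = np.atleast_2d(np.asarray(X, float))
    T, d = X.shape
    ll = 0.0
    m_pred, S_pred = m0, S0
    for t in range(T):
        # innovation
        y = X[t] - C @ m_pred
        S_inn = C @ S_pred @ C.T + R
        sign, logdet = np.linalg.slogdet(S_inn)
        if sign <= 0:
            raise np.linalg.LinAlgError("singular innovation covariance")
        sol = np.linalg.solve(S_inn, y)
        ll += -0.5 * (d * _LOG2PI + logdet + y @ sol)
        # update
        K = np.linalg.solve(S_inn, C @ S_pred).T
        m_filt = m_pred + K @ y
        S_filt = S_pred - K @ C @ S_pred
        # predict
        m_pred = A @ m_filt
        S_pred = A @ S_filt @ A.T + Q
    return float(ll)


def simulate_lgss(
    A, C, Q, R, m0, S0, T: int, n_seq: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate sequences from a linear-Gaussian state-space model.

    Returns (X, Z): observations (n_seq, T, d) and latents (n_seq, T, L).
    """
    A, C, Q, R = (np.atleast_2d(np.asarray(a, float)) for a in (A, C, Q, R))
    m0 = np.atleast_1d(np.asarray(m0, float))
    S0 = np.atleast_2d(np.asarray(S0, float))
    L, d = A.shape[0], C.shape[0]
    cQ, cR, cS0 = (np.linalg.cholesky(M) for M in (Q, R, S0))
    Z = np.empty((n_seq, T, L))
    X = np.empty((n_seq, T, d))
    for i in range(n_seq):
        z = m0 + cS0 @ rng.standard_normal(L)
        for t in range(T):
            if t > 0:
                z = A @ z + cQ @ rng.standard_normal(L)
            Z[i, t] = z
            X[i, t] = C @ z + cR @ rng.standard_normal(d)
    return X, Z
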