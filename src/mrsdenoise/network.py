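"""Compact CPU noise-prediction network for the diffusion denoiser.

The predictor maps a diffused 64x64 spectrum grid and a step index t to the
Gaussian noise it believes was mixed in.  The architecture is deliberately
small and written directly in numpy (forward pass, analytic backward pass,
Adam), so the whole package trains in seconds-to-minutes on one CPU core
and stays bit-reproducible under a fixed seed:

* a sinusoidal step embedding of t feeds every stage, so the network can
  behave differently at different noise levels;
* a *diagonal gain path* ``c(t) * x`` with ``log c = gamma + g(t)``
  (``gamma`` a learned per-cell vector, ``g(t)`` a learned scalar of the
  step embedding).  Because clean spectra are essentially zero outside the
  metabolite region, the optimal noise estimate there is a region- and
  step-dependent rescaling of the input, which this path expresses exactly;
* a two-hidden-layer fully connected residual path that handles the
  signal-bearing region, where noise and signal must be disentangled.

The class is intentionally generic over the flattened grid length; callers
interact with it only through the NoisePredictor contract
(:meth:`predict`), so any alternative architecture can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DenoiseMLP", "sinusoidal_embedding"]

_SQRT_2_OVER_PI = np.float32(np.sqrt(2.0 / np.pi))


def sinusoidal_embedding(t: np.ndarray, dim: int, t_max: int) -> np.ndarray:
    """Standard sin/cos positional embedding of step indices (B,) -> (B, dim)."""
    t = np.asarray(t, dtype=np.float32).reshape(-1, 1)
    half = dim // 2
    freqs = np.exp(-np.log(float(t_max)) * np.arange(half, dtype=np.float32) / max(half - 1, 1))
    ang = t * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1).astype(np.float32)


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + np.tanh(_SQRT_2_OVER_PI * (x + 0.044715 * x**3)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    u = _SQRT_2_OVER_PI * (x + 0.044715 * x**3)
    th = np.tanh(u)
    du = _SQRT_2_OVER_PI * (1.0 + 3 * 0.044715 * x**2)
    return 0.5 * (1.0 + th) + 0.5 * x * (1.0 - th**2) * du


@dataclass
class DenoiseMLP:
    """Noise predictor epsilon_theta(s_t, t) on flattened grids.

    Parameters are float32 numpy arrays; ``predict`` is deterministic given
    the parameters.  ``training_meta`` records epochs seen, the loss curve
    and the training seed.
    """

    n_in: int = 4096
    hidden: int = 256
    emb_dim: int = 32
    emb_hidden: int = 64
    t_max: int = 1000
    seed: int = 0
    params: dict = field(default_factory=dict)
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.params:
            self.params = self._init_params(np.random.default_rng(self.seed))
        self.training_meta.setdefault("epochs", 0)
        self.training_meta.setdefault("loss_curve", [])
        self.training_meta.setdefault("seed", self.seed)

    # ----- parameters -------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> dict:
        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        n, h, eh = self.n_in, self.hidden, self.emb_hidden
        return {
            # step-embedding trunk
            "We": he((self.emb_dim, eh), self.emb_dim),
            "be": np.zeros(eh, dtype=np.float32),
            # diagonal gain path: log c = gamma + (e @ wg + bg)
            "gamma": np.zeros(n, dtype=np.float32),
            "wg": np.zeros(eh, dtype=np.float32),
            "bg": np.zeros((), dtype=np.float32),
            # residual MLP path
            "W1": he((n, h), n), "b1": np.zeros(h, dtype=np.float32),
            "A1": he((eh, h), eh),
            "W2": he((h, h), h), "b2": np.zeros(h, dtype=np.float32),
            "A2": he((eh, h), eh),
            # near-zero output head: the network starts as (almost) pure gain
            "W3": (rng.standard_normal((h, n)) * 1e-3).astype(np.float32),
            "b3": np.zeros(n, dtype=np.float32),
        }

    # ----- forward / backward -----------------------------------------
    def _forward(self, x: np.ndarray, t: np.ndarray, cache: bool = False):
        p = self.params
        emb = sinusoidal_embedding(t, self.emb_dim, self.t_max)
        e = _gelu(emb @ p["We"] + p["be"])
        logc = p["gamma"][None, :] + (e @ p["wg"] + p["bg"])[:, None]
        logc = np.clip(logc, -12.0, 12.0)
        c = np.exp(logc)
        z1 = x @ p["W1"] + p["b1"] + e @ p["A1"]
        h1 = _gelu(z1)
        z2 = h1 @ p["W2"] + p["b2"] + e @ p["A2"]
        h2 = _gelu(z2)
        y = c * x + h2 @ p["W3"] + p["b3"]
        if not cache:
            return y
        return y, {"x": x, "emb": emb, "e": e, "c": c, "z1": z1, "h1": h1,
                   "z2": z2, "h2": h2,
                   "ze": emb @ p["We"] + p["be"]}

    def _backward(self, d_out: np.ndarray, cache: dict) -> dict:
        p = self.params
        x, e, c = cache["x"], cache["e"], cache["c"]
        g: dict[str, np.ndarray] = {}
        # gain path
        dc = d_out * x          # dL/dc
        dlogc = dc * c
        g["gamma"] = dlogc.sum(axis=0)
        ds = dlogc.sum(axis=1)  # per-sample scalar
        g["wg"] = e.T @ ds
        g["bg"] = ds.sum()
        de = np.outer(ds, p["wg"])
        # MLP path
        g["W3"] = cache["h2"].T @ d_out
        g["b3"] = d_out.sum(axis=0)
        dh2 = d_out @ p["W3"].T
        dz2 = dh2 * _gelu_grad(cache["z2"])
        g["W2"] = cache["h1"].T @ dz2
        g["b2"] = dz2.sum(axis=0)
        g["A2"] = e.T @ dz2
        de += dz2 @ p["A2"].T
        dh1 = dz2 @ p["W2"].T
        dz1 = dh1 * _gelu_grad(cache["z1"])
        g["W1"] = x.T @ dz1
        g["b1"] = dz1.sum(axis=0)
        g["A1"] = e.T @ dz1
        de += dz1 @ p["A1"].T
        # embedding trunk
        dze = de * _gelu_grad(cache["ze"])
        g["We"] = cache["emb"].T @ dze
        g["be"] = dze.sum(axis=0)
        return g

    # ----- public API --------------------------------------------------
    def predict(self, grid: np.ndarray, t) -> np.ndarray:
        """Predicted noise for grid(s) at step(s) t; shape-preserving."""
        arr = np.asarray(grid, dtype=np.float32)
        single = arr.ndim <= 2 and arr.size == self.n_in
        x = arr.reshape(-1, self.n_in)
        tt = np.broadcast_to(np.asarray(t, dtype=np.float32).reshape(-1), (x.shape[0],))
        out = self._forward(x, tt)
        return out.reshape(arr.shape) if single else out.reshape(np.shape(grid))

    def train_epochs(
        self,
        s0: np.ndarray,
        alpha_bar: np.ndarray,
        epochs: int = 20,
        batch: int = 32,
        lr: float = 1e-3,
        seed: int = 0,
    ) -> list[float]:
        """Adam training on the simplified noise-prediction objective.

        Each step draws t uniform on {1..T} and eps ~ N(0, I) per sample,
        forms s_t = sqrt(abar_t) s0 + sqrt(1 - abar_t) eps and minimizes
        mean squared error between eps and the prediction.  Returns the
        per-epoch loss curve (appended to ``training_meta``).  Raises on a
        non-finite loss.
        """
        s0 = np.asarray(s0, dtype=np.float32).reshape(-1, self.n_in)
        T = len(alpha_bar)
        ab = np.asarray(alpha_bar, dtype=np.float32)
        rng = np.random.default_rng(seed)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v) for k, v in self.params.items()}
        step = 0
        curve: list[float] = []
        for _ in range(epochs):
            order = rng.permutation(len(s0))
            losses = []
            for start in range(0, len(s0), batch):
                idx = order[start : start + batch]
                x0 = s0[idx]
                t = rng.integers(1, T + 1, size=len(idx))
                eps = rng.standard_normal(x0.shape).astype(np.float32)
                a = ab[t - 1][:, None]
                st = np.sqrt(a) * x0 + np.sqrt(1.0 - a) * eps
                pred, cache = self._forward(st, t.astype(np.float32), cache=True)
                resid = pred - eps
                loss = float(np.mean(resid**2))
                if not np.isfinite(loss):
                    raise FloatingPointError("training diverged (non-finite loss)")
                losses.append(loss)
                d_out = (2.0 / resid.size) * resid
                grads = self._backward(d_out.astype(np.float32), cache)
                step += 1
                b1, b2, epsa = 0.9, 0.999, 1e-8
                for k, gk in grads.items():
                    m[k] = b1 * m[k] + (1 - b1) * gk
                    v[k] = b2 * v[k] + (1 - b2) * gk**2
                    mhat = m[k] / (1 - b1**step)
                    vhat = v[k] / (1 - b2**step)
                    self.params[k] = (self.params[k] - lr * mhat / (np.sqrt(vhat) + epsa)).astype(np.float32)
            curve.append(float(np.mean(losses)))
        self.training_meta["epochs"] += epochs
        self.training_meta["loss_curve"].extend(curve)
        return curve

    # ----- persistence --------------------------------------------------
    def state_dict(self) -> dict:
        meta = dict(n_in=self.n_in, hidden=self.hidden, emb_dim=self.emb_dim,
                    emb_hidden=self.emb_hidden, t_max=self.t_max, seed=self.seed)
        return {"meta": meta, "params": dict(self.params),
                "training_meta": dict(self.training_meta)}

    @classmethod
    def from_state_dict(cls, state: dict) -> "DenoiseMLP":
        net = cls(**state["meta"], params=dict(state["params"]))
        net.training_meta.update(state.get("training_meta", {}))
        return net
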