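"""Dynamic convolutional autoencoder (DCAE), NumPy implementation.

Each encoder layer owns K parallel 1-D convolution kernels.  A small
attention network (global average of the layer input -> bottleneck ->
softmax) produces per-sample weights pi on the K-simplex; the layer
convolves with the aggregated kernel sum_k pi_k * w_k and bias
sum_k pi_k * b_k, applies a sigmoid and max-pools.  The decoder reuses each
layer's aggregated kernel transposed (tied weights, with the *input's*
attention), upsampling to invert the pooling.  Training minimises the mean
squared reconstruction error by plain gradient descent with hand-derived
backpropagation, layer-wise pretraining first and joint fine-tuning after.

With K=1 the attention weight is exactly 1 and the model collapses to an
ordinary convolutional autoencoder; ``dynamic=False`` runs that CAE path
explicitly and is bit-identical to the K=1 dynamic path under the same
initialisation.

The feature vectors are treated as single-channel 1-D signals; inputs are
min-max scaled to [0, 1] (the scaler is persisted with the model) and
zero-padded on the right to a pooling-compatible length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DcaeConfig:
    K: int = 4
    kernel_size: int = 3
    pool_size: int = 2
    n_layers: int = 2
    hidden_dim: int = 64
    learning_rate: float = 0.001
    epochs: int = 300
    batch_size: int = 32
    seed: int = 0
    dynamic: bool = True  # False = plain convolutional autoencoder (CAE)

    def __post_init__(self) -> None:
        if self.K < 1 or self.hidden_dim < 1 or self.n_layers < 1:
            raise ValueError("K, hidden_dim, n_layers must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same-padding convolution)")


@dataclass
class DcaeOutput:
    hidden: np.ndarray          # per-sample encoded vectors y
    reconstruction: np.ndarray  # x' on the original (unpadded, scaled) length
    loss_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# convolution primitives (per-sample kernels, 'same' zero padding)
# ---------------------------------------------------------------------------

def _conv_same(X: np.ndarray, Kb: np.ndarray) -> np.ndarray:
    """Cross-correlate each row of X with its own kernel row of Kb."""
    B, L = X.shape
    ks = Kb.shape[1]
    pad = ks // 2
    Xp = np.zeros((B, L + ks - 1))
    Xp[:, pad : pad + L] = X
    out = np.zeros((B, L))
    for k in range(ks):
        out += Kb[:, k : k + 1] * Xp[:, k : k + L]
    return out

def _conv_same_grad_input(dT: np.ndarray, Kb: np.ndarray) -> np.ndarray:
    return _conv_same(dT, Kb[:, ::-1])

def _conv_same_grad_kernel(dT: np.ndarray, X: np.ndarray, ks: int) -> np.ndarray:
    B, L = X.shape
    pad = ks // 2
    Xp = np.zeros((B, L + ks - 1))
    Xp[:, pad : pad + L] = X
    dK = np.zeros((B, ks))
    for k in range(ks):
        dK[:, k] = np.sum(dT * Xp[:, k : k + L], axis=1)
    return dK


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class DcaeModel:
    """Parameter container + forward/backward passes."""

    def __init__(self, cfg: DcaeConfig, input_len: int):
        self.cfg = cfg
        ps, nl = cfg.pool_size, cfg.n_layers
        factor = ps**nl
        self.input_len = input_len
        self.padded_len = int(np.ceil(input_len / factor) * factor)
        self.enc_len = self.padded_len // factor
        self.scaler_min: np.ndarray | None = None
        self.scaler_range: np.ndarray | None = None
        rng = np.random.default_rng(cfg.seed)
        ks, K = cfg.kernel_size, cfg.K
        self.layers: list[dict[str, np.ndarray]] = []
        # core parameters first so the CAE path shares the same draws
        for _ in range(nl):
            # near-identity init: the centre tap starts at 1 so the untrained
            # encoder already passes the signal through
            kernels = rng.normal(0.0, 0.1, size=(K, ks))
            kernels[:, ks // 2] += 1.0
            self.layers.append({"kernels": kernels, "biases": np.zeros(K)})
        he = 1.0 / np.sqrt(self.enc_len)
        self.enc_W = rng.normal(0.0, he, size=(cfg.hidden_dim, self.enc_len))
        self.enc_b = np.zeros(cfg.hidden_dim)
        hd = 1.0 / np.sqrt(cfg.hidden_dim)
        self.dec_W = rng.normal(0.0, hd, size=(self.enc_len, cfg.hidden_dim))
        self.dec_b = np.zeros(self.enc_len)
        if cfg.dynamic:
            a = max(K, 4)
            for layer in self.layers:
                layer["A1"] = rng.normal(0.0, 0.5, size=a)
                layer["c1"] = np.zeros(a)
                layer["A2"] = rng.normal(0.0, 0.5, size=(K, a))
                layer["c2"] = np.zeros(K)

    # -- attention ---------------------------------------------------------
    def attention_weights(self, x: np.ndarray, li: int) -> np.ndarray:
        """Per-sample simplex weights pi_k for layer ``li`` (batch input x)."""
        layer = self.layers[li]
        if not self.cfg.dynamic:
            return np.ones((x.shape[0], self.cfg.K)) / self.cfg.K
        s = x.mean(axis=1)
        h = np.maximum(s[:, None] * layer["A1"] + layer["c1"], 0.0)
        logits = h @ layer["A2"].T + layer["c2"]
        return _softmax(logits)

    # -- forward -----------------------------------------------------------
    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler_min is not None:
            X = (X - self.scaler_min) / self.scaler_range
            X = np.clip(X, 0.0, 1.0)
        B, L = X.shape
        if L != self.input_len:
            raise ValueError(f"expected input length {self.input_len}, got {L}")
        Xp = np.zeros((B, self.padded_len))
        Xp[:, :L] = X
        return Xp

    def forward(self, X_raw: np.ndarray) -> dict:
        cfg = self.cfg
        ps = cfg.pool_size
        X0 = self._prepare(X_raw)
        cache: dict = {"X0": X0, "enc": []}
        x = X0
        for li, layer in enumerate(self.layers):
            if cfg.dynamic:
                s = x.mean(axis=1)
                h = np.maximum(s[:, None] * layer["A1"] + layer["c1"], 0.0)
                logits = h @ layer["A2"].T + layer["c2"]
                pi = _softmax(logits)
                Kb = pi @ layer["kernels"]
                Bb = pi @ layer["biases"]
            else:
                B = x.shape[0]
                s = h = pi = None
                Kb = np.broadcast_to(layer["kernels"][0], (B, cfg.kernel_size)).copy()
                Bb = np.broadcast_to(layer["biases"][0], (B,)).copy()
            pre = _conv_same(x, Kb) + Bb[:, None]
            t = _sigmoid(pre)
            B, L = t.shape
            tr = t.reshape(B, L // ps, ps)
            arg = tr.argmax(axis=2)
            pooled = np.take_along_axis(tr, arg[:, :, None], axis=2)[:, :, 0]
            cache["enc"].append({
                "x": x, "s": s, "h": h, "pi": pi, "Kb": Kb, "Bb": Bb,
                "pre": pre, "t": t, "arg": arg,
            })
            x = pooled
        F = x  # (B, enc_len)
        y = F @ self.enc_W.T + self.enc_b
        cache["F"], cache["y"] = F, y
        # decoder
        u = y @ self.dec_W.T + self.dec_b
        cache["dec"] = []
        for li in range(cfg.n_layers - 1, -1, -1):
            e = cache["enc"][li]
            up = np.repeat(u, ps, axis=1)
            pre_d = _conv_same(up, e["Kb"][:, ::-1]) + e["Bb"][:, None]
            out = _sigmoid(pre_d)
            cache["dec"].append({"li": li, "u": u, "up": up, "pre": pre_d, "out": out})
            u = out
        cache["Xrec"] = u  # (B, padded_len)
        return cache

    # -- loss + backward ---------------------------------------------------
    def loss(self, cache: dict) -> float:
        L = self.input_len
        diff = cache["Xrec"][:, :L] - cache["X0"][:, :L]
        return float(np.mean(diff**2))

    def backward(self, cache: dict) -> dict:
        cfg = self.cfg
        ps, ks = cfg.pool_size, cfg.kernel_size
        B = cache["X0"].shape[0]
        L = self.input_len
        grads: dict = {
            "enc_W": np.zeros_like(self.enc_W), "enc_b": np.zeros_like(self.enc_b),
            "dec_W": np.zeros_like(self.dec_W), "dec_b": np.zeros_like(self.dec_b),
            "layers": [
                {k: np.zeros_like(v) for k, v in layer.items()} for layer in self.layers
            ],
        }
        dKb_acc = [np.zeros((B, ks)) for _ in self.layers]
        dBb_acc = [np.zeros(B) for _ in self.layers]
        # training objective: per-sample summed squared error, batch-averaged
        # (the reported loss trace is the per-position mean, a constant
        # multiple with the same minimiser; summing keeps gradient steps at
        # a useful size for the stated learning rate)
        dout = np.zeros_like(cache["Xrec"])
        dout[:, :L] = 2.0 * (cache["Xrec"][:, :L] - cache["X0"][:, :L]) / B
        # decoder stages in reverse of their execution
        for stage in reversed(cache["dec"]):
            li = stage["li"]
            e = cache["enc"][li]
            dpre = dout * stage["out"] * (1.0 - stage["out"])
            dBb_acc[li] += dpre.sum(axis=1)
            dKbf = _conv_same_grad_kernel(dpre, stage["up"], ks)
            dKb_acc[li] += dKbf[:, ::-1]
            dup = _conv_same_grad_input(dpre, e["Kb"][:, ::-1])
            du = dup.reshape(B, -1, ps).sum(axis=2)
            dout = du
        # du is now gradient w.r.t. the decoder input affine output
        grads["dec_W"] += dout.T @ cache["y"]
        grads["dec_b"] += dout.sum(axis=0)
        dy = dout @ self.dec_W
        grads["enc_W"] += dy.T @ cache["F"]
        grads["enc_b"] += dy.sum(axis=0)
        dF = dy @ self.enc_W
        # encoder layers, deepest first
        dpool = dF
        for li in range(cfg.n_layers - 1, -1, -1):
            e = cache["enc"][li]
            layer = self.layers[li]
            g = grads["layers"][li]
            Bn, Lp = e["t"].shape
            dT = np.zeros((Bn, Lp // ps, ps))
            np.put_along_axis(dT, e["arg"][:, :, None], dpool[:, :, None], axis=2)
            dT = dT.reshape(Bn, Lp)
            dpre = dT * e["t"] * (1.0 - e["t"])
            dBb = dBb_acc[li] + dpre.sum(axis=1)
            dKb = dKb_acc[li] + _conv_same_grad_kernel(dpre, e["x"], ks)
            dx = _conv_same_grad_input(dpre, e["Kb"])
            if cfg.dynamic:
                pi = e["pi"]
                g["kernels"] += pi.T @ dKb
                g["biases"] += pi.T @ dBb
                dpi = dKb @ layer["kernels"].T + dBb[:, None] * layer["biases"][None, :]
                dlogits = pi * (dpi - np.sum(dpi * pi, axis=1, keepdims=True))
                g["A2"] += dlogits.T @ e["h"]
                g["c2"] += dlogits.sum(axis=0)
                dh = (dlogits @ layer["A2"]) * (e["h"] > 0)
                g["A1"] += (dh * e["s"][:, None]).sum(axis=0)
                g["c1"] += dh.sum(axis=0)
                ds = dh @ layer["A1"]
                dx = dx + ds[:, None] / e["x"].shape[1]
            else:
                # matmul reduction keeps this bit-identical to the K=1
                # dynamic path (same BLAS summation order)
                ones = np.ones((1, Bn))
                g["kernels"][0] += (ones @ dKb)[0]
                g["biases"][0] += (ones @ dBb[:, None])[0, 0]
            dpool = dx
        return grads

    # -- inference ---------------------------------------------------------
    def encode(self, X_raw: np.ndarray) -> np.ndarray:
        """Hidden representation y for a batch of (unscaled) feature vectors."""
        return self.forward(np.asarray(X_raw, dtype=float))["y"]

    def reconstruct(self, X_raw: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(X_raw, dtype=float))["Xrec"][:, : self.input_len]

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint as an .npz container with a versioned header key."""
        arrays = {"__version__": np.array([1]), "__input_len__": np.array([self.input_len])}
        arrays["scaler_min"] = self.scaler_min
        arrays["scaler_range"] = self.scaler_range
        arrays["enc_W"], arrays["enc_b"] = self.enc_W, self.enc_b
        arrays["dec_W"], arrays["dec_b"] = self.dec_W, self.dec_b
        for li, layer in enumerate(self.layers):
            for k, v in layer.items():
                arrays[f"layer{li}_{k}"] = v
        import json
        from dataclasses import asdict
        arrays["__config__"] = np.frombuffer(json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "DcaeModel":
        import json
        data = np.load(path)
        cfg = DcaeConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = cls(cfg, int(data["__input_len__"][0]))
        model.scaler_min = data["scaler_min"]
        model.scaler_range = data["scaler_range"]
        model.enc_W, model.enc_b = data["enc_W"], data["enc_b"]
        model.dec_W, model.dec_b = data["dec_W"], data["dec_b"]
        for li, layer in enumerate(model.layers):
            for k in list(layer):
                layer[k] = data[f"layer{li}_{k}"]
        return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _apply_grads(model: DcaeModel, grads: dict, lr: float, trainable: set[str]) -> None:
    if "heads" in trainable:
        model.enc_W -= lr * grads["enc_W"]
        model.enc_b -= lr * grads["enc_b"]
        model.dec_W -= lr * grads["dec_W"]
        model.dec_b -= lr * grads["dec_b"]
    for li, (layer, g) in enumerate(zip(model.layers, grads["layers"])):
        if f"layer{li}" in trainable:
            for k in layer:
                layer[k] -= lr * g[k]


def train(features: np.ndarray, cfg: DcaeConfig | None = None) -> tuple[DcaeModel, DcaeOutput]:
    """Fit the autoencoder on a batch of feature vectors.

    Inputs are min-max scaled to [0, 1]; the scaler is stored on the model so
    ``encode`` can be applied to held-out vectors.  Training runs one
    pretraining phase per layer (only that layer plus the affine heads
    update) followed by joint fine-tuning, each phase an equal share of
    ``cfg.epochs``; within a phase, shuffled mini-batches of
    ``cfg.batch_size`` take plain gradient-descent steps.
    """
    cfg = cfg or DcaeConfig()
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D feature matrix with >= 2 samples")
    model = DcaeModel(cfg, X.shape[1])
    # global (single min/max) scaling to [0, 1]: preserves the relative
    # variance of the fused feature coordinates, which per-column scaling
    # would flatten into incompressible isotropic noise
    lo, hi = float(X.min()), float(X.max())
    model.scaler_min = np.full(X.shape[1], lo)
    model.scaler_range = np.full(X.shape[1], max(hi - lo, 1e-12))
    rng = np.random.default_rng(cfg.seed + 1)
    n = X.shape[0]
    phases: list[set[str]] = [{f"layer{li}", "heads"} for li in range(cfg.n_layers)]
    phases.append({f"layer{li}" for li in range(cfg.n_layers)} | {"heads"})
    per = max(cfg.epochs // len(phases), 1)
    budgets = [per] * (len(phases) - 1) + [max(cfg.epochs - per * (len(phases) - 1), 1)]
    trace: list[float] = []
    for trainable, epochs in zip(phases, budgets):
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                cache = model.forward(X[idx])
                grads = model.backward(cache)
                _apply_grads(model, grads, cfg.learning_rate, trainable)
            full = model.forward(X)
            ep_loss = model.loss(full)
            if not np.isfinite(ep_loss):
                raise FloatingPointError("NaN loss; lr too high")
            trace.append(ep_loss)
    final = model.forward(X)
    out = DcaeOutput(hidden=final["y"], reconstruction=final["Xrec"][:, : model.input_len], loss_trace=trace)
    return model, out
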