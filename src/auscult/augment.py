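"""Per-class variational-autoencoder synthesis for class balancing.

One VAE is trained per minority class on its CleanSignals and sampled from the
standard-normal latent prior to top the class up to its target count. The default
targets give every heart class +600 records and every minority lung class +630,
leaving the majority lung class untouched (1917 -> 8067 records overall).

The model is a small dense VAE (2500 -> 256 -> 64 -> latent 32, mirrored decoder
with a tanh output so samples respect the (-1, 1) amplitude contract) trained by
maximizing the ELBO: a mean-squared reconstruction term plus the analytic KL
divergence to N(0, I),

    KL = -1/2 * sum_i (1 + log s2_i - mu_i^2 - s2_i),

with the reparameterization z = mu + sigma * eps, eps ~ N(0, I).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nnet import Adam, Dense, zero_grads
from .preprocess import TARGET_LEN, TARGET_RATE, CleanSignal, RawRecord, normalize_amplitude
from .vocab import require_known

DEFAULT_LATENT_DIM = 32
DEFAULT_EPOCHS = 200
DEFAULT_BATCH = 32
DEFAULT_LR = 1e-3


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Analytic KL( N(mu, diag(exp(logvar))) || N(0, I) ), averaged over rows."""
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    logvar = np.atleast_2d(np.asarray(logvar, dtype=np.float64))
    per_row = -0.5 * np.sum(1.0 + logvar - mu ** 2 - np.exp(logvar), axis=1)
    return float(per_row.mean())


@dataclass
class VAEModel:
    """Encoder/decoder pair for one class."""

    label: str
    latent_dim: int
    enc1: Dense
    enc2: Dense
    mu_head: Dense
    logvar_head: Dense
    dec1: Dense
    dec2: Dense
    dec3: Dense
    recon_history: list[float] = field(default_factory=list)

    def _layers(self):
        return [self.enc1, self.enc2, self.mu_head, self.logvar_head,
                self.dec1, self.dec2, self.dec3]

    def encode(self, x: np.ndarray, train: bool = False):
        h = self.enc2.forward(self.enc1.forward(x, train), train)
        return self.mu_head.forward(h, train), self.logvar_head.forward(h, train)

    def decode(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        return self.dec3.forward(self.dec2.forward(self.dec1.forward(z, train), train), train)


def _build(label: str, latent_dim: int, rng) -> VAEModel:
    return VAEModel(
        label=label, latent_dim=latent_dim,
        enc1=Dense(TARGET_LEN, 256, activation="relu", rng=rng),
        enc2=Dense(256, 64, activation="relu", rng=rng),
        mu_head=Dense(64, latent_dim, rng=rng),
        logvar_head=Dense(64, latent_dim, rng=rng),
        dec1=Dense(latent_dim, 64, activation="relu", rng=rng),
        dec2=Dense(64, 256, activation="relu", rng=rng),
        dec3=Dense(256, TARGET_LEN, activation="tanh", rng=rng),
    )


def train_class_vae(signals, latent_dim: int = DEFAULT_LATENT_DIM,
                    epochs: int = DEFAULT_EPOCHS, batch_size: int = DEFAULT_BATCH,
                    learning_rate: float = DEFAULT_LR, seed: int = 0) -> VAEModel:
    """Train a VAE on the CleanSignals of a single class."""
    signals = list(signals)
    if len(signals) < 2:
        raise ValueError("need at least 2 signals to train a VAE")
    labels = {s.label for s in signals}
    if len(labels) != 1:
        raise ValueError(f"mixed-class input {sorted(labels)}; train one VAE per class")
    label = signals[0].label
    x_all = np.stack([s.samples for s in signals]).astype(np.float32)

    rng = np.random.default_rng(seed)
    model = _build(label, latent_dim, rng)
    layers = model._layers()
    opt = Adam([p for lay in layers for p in lay.params()], lr=learning_rate)

    n = x_all.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        recon_sum = 0.0
        for start in range(0, n, batch_size):
            xb = x_all[order[start:start + batch_size]]
            b = xb.shape[0]
            zero_grads(layers)
            mu, logvar = model.encode(xb, train=True)
            logvar = np.clip(logvar, -10.0, 10.0)
            sigma = np.exp(0.5 * logvar)
            eps = rng.standard_normal(mu.shape).astype(np.float32)
            z = mu + sigma * eps
            xhat = model.decode(z, train=True)

            diff = xhat - xb
            recon = float((diff ** 2).sum() / b)
            recon_sum += recon * b
            # d(mean recon)/d xhat
            dxhat = (2.0 / b) * diff
            dz = model.dec1.backward(model.dec2.backward(model.dec3.backward(dxhat)))
            # KL gradients (mean over batch) + reparameterization path
            dmu = dz + mu / b
            dlogvar = dz * eps * 0.5 * sigma + (np.exp(logvar) - 1.0) / (2.0 * b)
            dh = model.mu_head.backward(dmu.astype(np.float32)) \
                + model.logvar_head.backward(dlogvar.astype(np.float32))
            model.enc1.backward(model.enc2.backward(dh))
            opt.step()
        model.recon_history.append(recon_sum / n)
    return model


def synthesize(vae: VAEModel, k: int, seed: int = 0) -> list[CleanSignal]:
    """Decode ``k`` latent draws from N(0, I) into synthetic CleanSignals."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return []
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((k, vae.latent_dim)).astype(np.float32)
    xhat = vae.decode(z)
    out = []
    for i in range(k):
        rec = RawRecord(samples=xhat[i].astype(np.float64), rate=TARGET_RATE,
                        label=vae.label, source_id=f"vae-{vae.label}-{i:04d}")
        out.append(normalize_amplitude(rec, synthetic=True))
    return out


@dataclass
class AugmentationPlan:
    """Per-class target counts; defaults to the published balancing scheme."""

    targets: dict[str, int]

    def __post_init__(self) -> None:
        for c in self.targets:
            require_known(c)

    @classmethod
    def default(cls) -> "AugmentationPlan":
        from .vocab import BALANCED_COUNTS
        return cls(targets=dict(BALANCED_COUNTS))

    @classmethod
    def from_csv(cls, path) -> "AugmentationPlan":
        import pandas as pd
        df = pd.read_csv(path)
        return cls(targets={str(r["class"]): int(r["target"]) for _, r in df.iterrows()})


def balance(signals, plan: AugmentationPlan | None = None, seed: int = 0,
            latent_dim: int = DEFAULT_LATENT_DIM, epochs: int = DEFAULT_EPOCHS,
            batch_size: int = DEFAULT_BATCH) -> list[CleanSignal]:
    """Top every class up to its plan target with VAE samples.

    Originals are passed through unmodified; synthetic records carry
    ``synthetic=True``. Classes already at target train no VAE at all, so applying
    the same plan twice is a no-op the second time.
    """
    signals = list(signals)
    plan = plan or AugmentationPlan.default()
    by_class: dict[str, list[CleanSignal]] = {}
    for s in signals:
        by_class.setdefault(s.label, []).append(s)

    out = list(signals)
    for ci, (cls, target) in enumerate(sorted(plan.targets.items())):
        have = len(by_class.get(cls, []))
        if target < have:
            raise ValueError(f"plan target {target} below current count {have} for {cls}")
        deficit = target - have
        if deficit == 0:
            continue
        if have == 0:
            raise ValueError(f"cannot synthesize class {cls}: no real records")
        child = np.random.SeedSequence(entropy=seed, spawn_key=(ci,))
        train_seed, synth_seed = child.generate_state(2) % (2 ** 31)
        vae = train_class_vae(by_class[cls], latent_dim=latent_dim, epochs=epochs,
                              batch_size=batch_size, seed=int(train_seed))
        out.extend(synthesize(vae, deficit, seed=int(synth_seed)))
    return out
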