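"""ctGAN core: generator/discriminator architectures and the four losses.

Two generators map whole feature vectors (selected genes plus the
log2(time + 1) feature) between cancer domains A and B; two least-squares
discriminators judge domain membership. The objective combines the two
adversarial terms with L1 cycle-consistency and identity penalties:

    L = L_GAN(G_AB, D_B) + L_GAN(G_BA, D_A) + lam_cyc * L_cycle + lam_id * L_identity

Setting ``lam_identity = 0`` gives the identity-loss ablation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .nn import Dense, BatchNorm, ReLU, LeakyReLU, Sequential, Residual

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "LossTerms",
    "CtganModel",
    "build_generator",
    "build_discriminator",
    "lsgan_loss",
    "cycle_loss",
    "identity_loss",
    "total_loss",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Residual MLP mapping R^d -> R^d, d = n_genes + 1 (the time feature)."""

    input_dim: int
    hidden_width: int = 256
    n_residual_blocks: int = 3

    def __post_init__(self):
        if self.input_dim <= 0 or self.hidden_width <= 0 or self.n_residual_blocks < 0:
            raise ValueError(f"invalid generator spec {self}")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Three leaky-ReLU hidden layers, scalar linear output (LSGAN: no squashing)."""

    input_dim: int
    hidden_widths: tuple[int, int, int] = (256, 128, 64)
    leaky_slope: float = 0.2

    def __post_init__(self):
        if self.input_dim <= 0 or len(self.hidden_widths) != 3 or min(self.hidden_widths) <= 0:
            raise ValueError(f"invalid discriminator spec {self}")
        if not 0 <= self.leaky_slope < 1:
            raise ValueError(f"leaky slope must be in [0, 1), got {self.leaky_slope}")


@dataclass(frozen=True)
class LossTerms:
    """The four scalar objective components and their weighted total."""

    gan_ab: float
    gan_ba: float
    cycle: float
    identity: float
    lam_cycle: float = 1.0
    lam_identity: float = 1.0

    @property
    def total(self) -> float:
        return total_loss(self, self.lam_cycle, self.lam_identity)


def build_generator(spec: GeneratorSpec, seed: int) -> Sequential:
    """Generator of the domain-translation map.

    [dense + BN + ReLU] x2 -> residual block x3 -> [dense + BN + ReLU] x2
    -> linear dense back to the input dimension. Each residual block is
    y = x + BN(dense(ReLU(BN(dense(x))))) at constant width, with no
    activation after the skip addition. Output is linear: log-scale
    features are unbounded above and clipping happens only at export.
    """
    rng = np.random.default_rng(seed)
    d, h = spec.input_dim, spec.hidden_width
    layers = [Dense(d, h, rng), BatchNorm(h), ReLU(),
              Dense(h, h, rng), BatchNorm(h), ReLU()]
    for _ in range(spec.n_residual_blocks):
        inner = Sequential([Dense(h, h, rng), BatchNorm(h), ReLU(),
                            Dense(h, h, rng), BatchNorm(h)])
        layers.append(Residual(inner))
    layers += [Dense(h, h, rng), BatchNorm(h), ReLU(),
               Dense(h, h, rng), BatchNorm(h), ReLU(),
               Dense(h, d, rng)]
    return Sequential(layers)


def build_discriminator(spec: DiscriminatorSpec, seed: int) -> Sequential:
    """[dense + leaky ReLU] x3 -> dense(1, linear)."""
    rng = np.random.default_rng(seed)
    w1, w2, w3 = spec.hidden_widths
    return Sequential([
        Dense(spec.input_dim, w1, rng), LeakyReLU(spec.leaky_slope),
        Dense(w1, w2, rng), LeakyReLU(spec.leaky_slope),
        Dense(w2, w3, rng), LeakyReLU(spec.leaky_slope),
        Dense(w3, 1, rng),
    ])


def lsgan_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """Least-squares adversarial loss: E[(D(real) - 1)^2] + E[D(fake)^2]."""
    d_real = np.asarray(d_real, dtype=float).ravel()
    d_fake = np.asarray(d_fake, dtype=float).ravel()
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("lsgan_loss requires nonempty batches")
    return float(np.mean((d_real - 1.0) ** 2) + np.mean(d_fake ** 2))


def _mean_l1(x: np.ndarray, y: np.ndarray) -> float:
    x, y = np.atleast_2d(x), np.atleast_2d(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    # L1 over features, mean over samples: empirical E[||. - .||_1]
    return float(np.abs(x - y).sum(axis=1).mean())


def cycle_loss(a: np.ndarray, a_rec: np.ndarray, b: np.ndarray, b_rec: np.ndarray) -> float:
    """E[||G_BA(G_AB(a)) - a||_1] + E[||G_AB(G_BA(b)) - b||_1]."""
    return _mean_l1(a, a_rec) + _mean_l1(b, b_rec)


def identity_loss(b: np.ndarray, g_ab_of_b: np.ndarray,
                  a: np.ndarray, g_ba_of_a: np.ndarray) -> float:
    """E[||G_AB(b) - b||_1] + E[||G_BA(a) - a||_1]."""
    return _mean_l1(b, g_ab_of_b) + _mean_l1(a, g_ba_of_a)


def total_loss(terms: LossTerms, lam_cycle: float = 1.0, lam_identity: float = 1.0) -> float:
    """Weighted full objective; the plain four-term sum at unit weights."""
    if lam_cycle < 0 or lam_identity < 0:
        raise ValueError("loss weights must be nonnegative")
    return float(terms.gan_ab + terms.gan_ba
                 + lam_cycle * terms.cycle + lam_identity * terms.identity)


class CtganModel:
    """The four networks G_AB, G_BA, D_A, D_B plus their specs and gene list."""

    def __init__(self, gen_spec: GeneratorSpec, disc_spec: DiscriminatorSpec,
                 gene_ids: list[str], seed: int = 0):
        if gen_spec.input_dim != disc_spec.input_dim:
            raise ValueError("generator and discriminator input dimensions differ")
        if gen_spec.input_dim != len(gene_ids) + 1:
            raise ValueError(
                f"input_dim {gen_spec.input_dim} must equal n_genes + 1 = {len(gene_ids) + 1}")
        self.gen_spec = gen_spec
        self.disc_spec = disc_spec
        self.gene_ids = list(gene_ids)
        self.seed = seed
        self.g_ab = build_generator(gen_spec, seed)
        self.g_ba = build_generator(gen_spec, seed + 1)
        self.d_a = build_discriminator(disc_spec, seed + 2)
        self.d_b = build_discriminator(disc_spec, seed + 3)
        self.train_config: dict = {}

    @property
    def networks(self):
        return {"g_ab": self.g_ab, "g_ba": self.g_ba, "d_a": self.d_a, "d_b": self.d_b}

    # -- checkpointing: one .npz archive holding weights, BN stats and specs --

    def _state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for net_name, net in self.networks.items():
            for i, layer in enumerate(net.layers):
                prefix = f"{net_name}.{i}"
                self._collect(layer, prefix, out)
        return out

    @staticmethod
    def _collect(layer, prefix, out):
        if isinstance(layer, Dense):
            out[f"{prefix}.W"] = layer.W.value
            out[f"{prefix}.b"] = layer.b.value
        elif isinstance(layer, BatchNorm):
            out[f"{prefix}.gamma"] = layer.gamma.value
            out[f"{prefix}.beta"] = layer.beta.value
            out[f"{prefix}.rmean"] = layer.running_mean
            out[f"{prefix}.rvar"] = layer.running_var
        elif isinstance(layer, Residual):
            for j, inner in enumerate(layer.inner.layers):
                CtganModel._collect(inner, f"{prefix}.res{j}", out)

    @staticmethod
    def _restore(layer, prefix, arrays):
        if isinstance(layer, Dense):
            layer.W.value[...] = arrays[f"{prefix}.W"]
            layer.b.value[...] = arrays[f"{prefix}.b"]
        elif isinstance(layer, BatchNorm):
            layer.gamma.value[...] = arrays[f"{prefix}.gamma"]
            layer.beta.value[...] = arrays[f"{prefix}.beta"]
            layer.running_mean[...] = arrays[f"{prefix}.rmean"]
            layer.running_var[...] = arrays[f"{prefix}.rvar"]
        elif isinstance(layer, Residual):
            for j, inner in enumerate(layer.inner.layers):
                CtganModel._restore(inner, f"{prefix}.res{j}", arrays)

    def save(self, path) -> None:
        meta = json.dumps({
            "gen_spec": asdict(self.gen_spec),
            "disc_spec": asdict(self.disc_spec),
            "gene_ids": self.gene_ids,
            "seed": self.seed,
            "train_config": self.train_config,
        })
        np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                            **self._state_arrays())

    @classmethod
    def load(cls, path) -> "CtganModel":
        with np.load(path) as arc:
            meta = json.loads(bytes(arc["__meta__"]).decode())
            arrays = {k: arc[k] for k in arc.files if k != "__meta__"}
        gspec = GeneratorSpec(**meta["gen_spec"])
        dspec_kw = dict(meta["disc_spec"])
        dspec_kw["hidden_widths"] = tuple(dspec_kw["hidden_widths"])
        model = cls(gspec, DiscriminatorSpec(**dspec_kw), meta["gene_ids"], meta["seed"])
        model.train_config = meta["train_config"]
        for net_name, net in model.networks.items():
            for i, layer in enumerate(net.layers):
                cls._restore(layer, f"{net_name}.{i}", arrays)
        return model
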