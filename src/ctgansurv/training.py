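"""Adversarial training with the asymmetric generator/discriminator schedule.

Training stability is handled by giving the generators three updates for
every discriminator update and by repeating the whole epoch schedule three
times consecutively on the same data without re-initialisation. GAN terms
use mean-squared (least-squares) targets; cycle and identity terms use L1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .ctgan import CtganModel, LossTerms, lsgan_loss, cycle_loss, identity_loss
from .data import DomainDataset
from .nn import Adam

logger = logging.getLogger("ctgansurv")

__all__ = ["TrainConfig", "train"]


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 64
    g_steps_per_d_step: int = 3
    n_repeats: int = 3
    lam_cycle: float = 1.0
    lam_identity: float = 1.0
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    seed: int = 0
    # 'batch': interleave G/D updates within each minibatch (default);
    # 'epoch': run g_steps_per_d_step generator-only epochs per discriminator epoch
    schedule: str = "batch"
    # 'continue': repeats resume from current weights; 'restart' re-initialises
    repeat_mode: str = "continue"

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.g_steps_per_d_step, self.n_repeats) < 0:
            raise ValueError("counts must be nonnegative")
        if self.batch_size == 0 or self.g_steps_per_d_step == 0 or self.n_repeats == 0:
            raise ValueError("batch_size, g_steps_per_d_step and n_repeats must be positive")
        if self.lam_cycle < 0 or self.lam_identity < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.schedule not in ("batch", "epoch"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.repeat_mode not in ("continue", "restart"):
            raise ValueError(f"unknown repeat_mode {self.repeat_mode!r}")


def _batches(n_large: int, n_small: int, batch_size: int, rng: np.random.Generator):
    """Index batches over the larger domain; the smaller is cycled, reshuffled."""
    order_large = rng.permutation(n_large)
    reps = -(-n_large // n_small)  # ceil
    order_small = np.concatenate([rng.permutation(n_small) for _ in range(reps)])[:n_large]
    for start in range(0, n_large, batch_size):
        yield order_large[start:start + batch_size], order_small[start:start + batch_size]


def _check_finite(value: float, what: str, epoch: int):
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite {what} loss at epoch {epoch}; "
                                 "lower the learning rate or widen the batch")


def train(model: CtganModel, domain_a: DomainDataset, domain_b: DomainDataset,
          cfg: TrainConfig) -> list[LossTerms]:
    """Train in place; returns per-epoch loss history (length epochs * n_repeats)."""
    xa_all = domain_a.model_matrix()
    xb_all = domain_b.model_matrix()
    if xa_all.shape[1] != xb_all.shape[1]:
        raise ValueError(f"domain feature dimensions differ: {xa_all.shape[1]} vs {xb_all.shape[1]}")
    if xa_all.shape[1] != model.gen_spec.input_dim:
        raise ValueError(f"model expects dimension {model.gen_spec.input_dim}, "
                         f"data has {xa_all.shape[1]}")
    if list(domain_a.expression.gene_ids) != model.gene_ids or \
       list(domain_b.expression.gene_ids) != model.gene_ids:
        raise ValueError("both domains must be restricted to the model's gene list")

    rng = np.random.default_rng(cfg.seed)
    g_params = model.g_ab.params + model.g_ba.params
    d_params = model.d_a.params + model.d_b.params
    opt_g = Adam(g_params, cfg.learning_rate, cfg.adam_beta1, cfg.adam_beta2)
    opt_d = Adam(d_params, cfg.learning_rate, cfg.adam_beta1, cfg.adam_beta2)

    history: list[LossTerms] = []
    # swap so 'large' drives the epoch; generators/discriminators stay tied to A/B
    a_large = xa_all.shape[0] >= xb_all.shape[0]

    for rep in range(cfg.n_repeats):
        if rep and cfg.repeat_mode == "restart":
            fresh = CtganModel(model.gen_spec, model.disc_spec, model.gene_ids,
                               model.seed + 101 * rep)
            for name, net in fresh.networks.items():
                mine = model.networks[name]
                for p_new, p_old in zip(net.params, mine.params):
                    p_old.value[...] = p_new.value
            opt_g = Adam(g_params, cfg.learning_rate, cfg.adam_beta1, cfg.adam_beta2)
            opt_d = Adam(d_params, cfg.learning_rate, cfg.adam_beta1, cfg.adam_beta2)
        for epoch in range(cfg.epochs):
            sums = np.zeros(4)
            n_batches = 0
            large, small = (xa_all, xb_all) if a_large else (xb_all, xa_all)
            for idx_l, idx_s in _batches(large.shape[0], small.shape[0],
                                         cfg.batch_size, rng):
                xa = large[idx_l] if a_large else small[idx_s]
                xb = small[idx_s] if a_large else large[idx_l]
                if cfg.schedule == "batch":
                    for _ in range(cfg.g_steps_per_d_step):
                        _generator_step(model, opt_g, xa, xb, cfg)
                    terms = _discriminator_step(model, opt_d, xa, xb, cfg)
                else:  # epoch-interleaved: D updated only on a subset of epochs
                    _generator_step(model, opt_g, xa, xb, cfg)
                    if epoch % cfg.g_steps_per_d_step == cfg.g_steps_per_d_step - 1:
                        terms = _discriminator_step(model, opt_d, xa, xb, cfg)
                    else:
                        terms = _measure(model, xa, xb, cfg)
                sums += [terms.gan_ab, terms.gan_ba, terms.cycle, terms.identity]
                n_batches += 1
            mean = sums / max(n_batches, 1)
            epoch_terms = LossTerms(*mean, cfg.lam_cycle, cfg.lam_identity)
            _check_finite(epoch_terms.total, "total", epoch)
            history.append(epoch_terms)
            logger.debug("rep %d epoch %d: gan_ab=%.4f gan_ba=%.4f cycle=%.4f id=%.4f",
                         rep, epoch, *mean)
    model.train_config = asdict(cfg)
    return history


def _generator_step(model: CtganModel, opt_g: Adam, xa: np.ndarray, xb: np.ndarray,
                    cfg: TrainConfig) -> None:
    """One Adam step on both generators; discriminators frozen."""
    opt_g.zero_grad()
    na, nb = xa.shape[0], xb.shape[0]

    fake_b, c_ab = model.g_ab.forward(xa, training=True)
    fake_a, c_ba = model.g_ba.forward(xb, training=True)
    rec_a, c_rec_a = model.g_ba.forward(fake_b, training=True)
    rec_b, c_rec_b = model.g_ab.forward(fake_a, training=True)

    db_fake, c_db = model.d_b.forward(fake_b, training=True)
    da_fake, c_da = model.d_a.forward(fake_a, training=True)

    # adversarial targets for G: generated samples should score as real (1)
    d_fake_b = model.d_b.backward(c_db, 2.0 * (db_fake - 1.0) / na)
    d_fake_a = model.d_a.backward(c_da, 2.0 * (da_fake - 1.0) / nb)
    for p in model.d_a.params + model.d_b.params:
        p.grad[...] = 0.0  # discriminators carried gradient only as a conduit

    # cycle: L1, sum over features, mean over samples
    g_rec_a = cfg.lam_cycle * np.sign(rec_a - xa) / na
    g_rec_b = cfg.lam_cycle * np.sign(rec_b - xb) / nb
    d_fake_b = d_fake_b + model.g_ba.backward(c_rec_a, g_rec_a)
    d_fake_a = d_fake_a + model.g_ab.backward(c_rec_b, g_rec_b)

    model.g_ab.backward(c_ab, d_fake_b)
    model.g_ba.backward(c_ba, d_fake_a)

    if cfg.lam_identity > 0:
        id_b, c_id_b = model.g_ab.forward(xb, training=True)
        id_a, c_id_a = model.g_ba.forward(xa, training=True)
        model.g_ab.backward(c_id_b, cfg.lam_identity * np.sign(id_b - xb) / nb)
        model.g_ba.backward(c_id_a, cfg.lam_identity * np.sign(id_a - xa) / na)

    opt_g.step()


def _discriminator_step(model: CtganModel, opt_d: Adam, xa: np.ndarray, xb: np.ndarray,
                        cfg: TrainConfig) -> LossTerms:
    """One Adam step on both discriminators against detached fakes."""
    opt_d.zero_grad()
    fake_b = model.g_ab(xa, training=True)
    fake_a = model.g_ba(xb, training=True)

    da_real, c_ar = model.d_a.forward(xa, training=True)
    da_fake, c_af = model.d_a.forward(fake_a, training=True)
    db_real, c_br = model.d_b.forward(xb, training=True)
    db_fake, c_bf = model.d_b.forward(fake_b, training=True)

    model.d_a.backward(c_ar, 2.0 * (da_real - 1.0) / xa.shape[0])
    model.d_a.backward(c_af, 2.0 * da_fake / fake_a.shape[0])
    model.d_b.backward(c_br, 2.0 * (db_real - 1.0) / xb.shape[0])
    model.d_b.backward(c_bf, 2.0 * db_fake / fake_b.shape[0])
    opt_d.step()

    return _loss_terms(model, xa, xb, fake_a, fake_b,
                       da_real, da_fake, db_real, db_fake, cfg)


def _measure(model: CtganModel, xa: np.ndarray, xb: np.ndarray, cfg: TrainConfig) -> LossTerms:
    fake_b = model.g_ab(xa, training=True)
    fake_a = model.g_ba(xb, training=True)
    da_real = model.d_a(xa, training=True)
    da_fake = model.d_a(fake_a, training=True)
    db_real = model.d_b(xb, training=True)
    db_fake = model.d_b(fake_b, training=True)
    return _loss_terms(model, xa, xb, fake_a, fake_b,
                       da_real, da_fake, db_real, db_fake, cfg)


def _loss_terms(model, xa, xb, fake_a, fake_b, da_real, da_fake, db_real, db_fake,
                cfg) -> LossTerms:
    rec_a = model.g_ba(fake_b, training=True)
    rec_b = model.g_ab(fake_a, training=True)
    id_b = model.g_ab(xb, training=True)
    id_a = model.g_ba(xa, training=True)
    return LossTerms(
        gan_ab=lsgan_loss(db_real, db_fake),
        gan_ba=lsgan_loss(da_real, da_fake),
        cycle=cycle_loss(xa, rec_a, xb, rec_b),
        identity=identity_loss(xb, id_b, xa, id_a),
        lam_cycle=cfg.lam_cycle,
        lam_identity=cfg.lam_identity,
    )
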