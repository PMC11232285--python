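"""Generation, reconstruction, and augmented-dataset assembly.

A trained model maps each source sample (expression + log2(time + 1)) into
the target domain's style. The output vector is split back into expression
(clipped at 0: log2(FPKM + 1) is nonnegative) and a time feature that is
inverted to days with a 1-day floor, mirroring the removal of 0-day
samples upstream. Event indicators are never generated: censoring status
travels with the source patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ctgan import CtganModel
from .data import DomainDataset, ExpressionMatrix

logger = logging.getLogger("ctgansurv")

__all__ = ["TransferResult", "generate", "reconstruct", "augment"]

_DIRECTIONS = {"AB": ("g_ab",), "BA": ("g_ba",)}
_CYCLES = {"ABA": ("g_ab", "g_ba"), "BAB": ("g_ba", "g_ab")}


@dataclass
class TransferResult:
    generated_expression: ExpressionMatrix
    generated_time_days: np.ndarray
    source_events: np.ndarray
    source_sample_ids: list[str]
    mode: str  # 'joint' or 'expression_only'
    n_clipped: int = 0  # negative expression entries clipped at export

    def __post_init__(self):
        if self.mode not in ("joint", "expression_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if (self.generated_time_days < 1.0 - 1e-12).any():
            raise ValueError("generated times must be >= 1 day")


def _check_genes(model: CtganModel, source: DomainDataset):
    if list(source.expression.gene_ids) != model.gene_ids:
        raise ValueError("source gene list does not match the model's gene list")


def _split_output(out: np.ndarray, gene_ids, sample_ids):
    expr_vals = out[:, :-1]
    n_clipped = int((expr_vals < 0).sum())
    if n_clipped:
        logger.info("clipped %d negative generated expression entries to 0", n_clipped)
    expr = ExpressionMatrix(list(sample_ids), list(gene_ids),
                            np.maximum(expr_vals, 0.0), normalized=True)
    days = np.maximum(np.exp2(out[:, -1]) - 1.0, 1.0)
    return expr, days, n_clipped


def generate(model: CtganModel, source: DomainDataset, direction: str = "AB",
             mode: str = "joint") -> TransferResult:
    """Translate every source sample into the other domain's style.

    ``direction`` is ``"AB"`` or ``"BA"``. In ``joint`` mode the generated
    survival time is used; ``expression_only`` keeps each source patient's
    real time (the ablation that transfers expression alone).
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be 'AB' or 'BA', got {direction!r}")
    _check_genes(model, source)
    net = model.networks[_DIRECTIONS[direction][0]]
    out = net(source.model_matrix(), training=False)  # running BN stats
    expr, days, n_clipped = _split_output(out, model.gene_ids, source.sample_ids)
    if mode == "expression_only":
        days = source.times.copy()
    return TransferResult(expr, days, source.events.copy(),
                          list(source.sample_ids), mode, n_clipped)


def reconstruct(model: CtganModel, source: DomainDataset, direction: str = "ABA"):
    """Round trip through both generators; returns (ExpressionMatrix, days)."""
    if direction not in _CYCLES:
        raise ValueError(f"direction must be 'ABA' or 'BAB', got {direction!r}")
    _check_genes(model, source)
    first, second = (model.networks[k] for k in _CYCLES[direction])
    out = second(first(source.model_matrix(), training=False), training=False)
    expr, days, _ = _split_output(out, model.gene_ids, source.sample_ids)
    return expr, days


def augment(real_target: DomainDataset, transfer: TransferResult) -> DomainDataset:
    """Real target rows first, then generated rows with 'gen:'-prefixed IDs."""
    if list(real_target.expression.gene_ids) != list(transfer.generated_expression.gene_ids):
        raise ValueError("gene lists of real and generated data differ")
    gen = transfer.generated_expression
    if gen.shape[0] == 0:
        return real_target
    ids = real_target.sample_ids + [f"gen:{s}" for s in transfer.source_sample_ids]
    values = np.vstack([real_target.expression.values, gen.values])
    expr = ExpressionMatrix(ids, list(real_target.expression.gene_ids), values,
                            normalized=real_target.expression.normalized)
    times = np.concatenate([real_target.times, transfer.generated_time_days])
    events = np.concatenate([real_target.events, transfer.source_events])
    return DomainDataset(real_target.name, expr, times, events)
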