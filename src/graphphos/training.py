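"""Dataset assembly, splits, the training loop, and evaluation metrics.

Positives are the annotated phosphosites; negatives are drawn from the
remaining S/T/Y positions so that the global negative count equals the
global positive count, stratified per residue type (S negatives matched to
S positives, and so on).  Splits are protein-level: uniformly random,
family-disjoint (larger families assigned to training first), or by mean
pLDDT (structure-confidence halves).

Training minimizes binary cross-entropy on the balanced site sets with
Adam (initial learning rate 1e-3), stepping one protein graph at a time
since graph sizes vary.  A seeded validation carve-out from the training
proteins selects the best checkpoint by F1.  Metrics are micro-averaged:
confusion counts are pooled over proteins before computing
accuracy / precision / sensitivity / F1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .feature_encoding import FeatureMatrix
from .model import (ModelConfig, PredictionResult, SiteSet, UNKNOWN_LABEL,
                    forward, forward_logits, init_params)
from .structure_graph import ContactGraph

logger = logging.getLogger(__name__)

DEFAULT_LR = 1e-3
DEFAULT_EPOCHS = 40
DEFAULT_VAL_FRACTION = 0.1
#: per-step Gaussian jitter added to inputs during training; regularizes the
#: one-protein-per-step regime against memorizing individual residues
DEFAULT_FEATURE_NOISE = 0.1
DEFAULT_EMBEDDING_NOISE = 1.0
#: the initial learning rate is halved this many times over a run
LR_DECAY_STEPS = 4


@dataclass
class ProteinExample:
    """Everything the model needs for one protein."""

    protein_id: str
    sequence: str
    features: np.ndarray          # L x 57
    graph: ContactGraph
    embeddings: np.ndarray        # L x p
    site_set: SiteSet

    def __post_init__(self):
        self.features = np.asarray(
            self.features.values if isinstance(self.features, FeatureMatrix)
            else self.features, dtype=np.float64)


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0

    @property
    def pre(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 0.0

    @property
    def sn(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def f1(self) -> float:
        denom = self.pre + self.sn
        return 2.0 * self.pre * self.sn / denom if denom else 0.0

    def as_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
                "acc": self.acc, "pre": self.pre, "sn": self.sn, "f1": self.f1}


# ---------------------------------------------------------------------------
# balanced site sampling
# ---------------------------------------------------------------------------

def build_balanced_sites(proteins: Sequence[tuple[str, str, set]],
                         seed: int, stratify: bool = True) -> dict[str, SiteSet]:
    """Balanced labeled site sets across a corpus.

    ``proteins`` is a sequence of (protein_id, sequence, positive_indices)
    with 0-based positive positions.  Negatives are sampled globally
    without replacement so the corpus-wide negative count equals the
    positive count, per residue type when ``stratify`` is on.
    """
    rng = np.random.default_rng(seed)
    positives: dict[str, list[tuple[str, int]]] = {"S": [], "T": [], "Y": []}
    candidates: dict[str, list[tuple[str, int]]] = {"S": [], "T": [], "Y": []}
    for pid, seq, pos in proteins:
        seq = seq.upper()
        for i in sorted(pos):
            aa = seq[i]
            if aa not in positives:
                raise ValueError(f"{pid}: annotated site {i} is {aa!r}, not S/T/Y")
            positives[aa].append((pid, i))
        for i, aa in enumerate(seq):
            if aa in candidates and i not in pos:
                candidates[aa].append((pid, i))

    if not stratify:
        positives = {"S": sum(positives.values(), [])}
        candidates = {"S": sum(candidates.values(), [])}

    chosen: list[tuple[str, int]] = []
    for aa in sorted(positives):
        n_pos, pool = len(positives[aa]), candidates[aa]
        if len(pool) < n_pos:
            warnings.warn(
                f"residue type {aa}: only {len(pool)} negative candidates for "
                f"{n_pos} positives; taking all", stacklevel=2)
            chosen.extend(pool)
        else:
            idx = rng.choice(len(pool), size=n_pos, replace=False)
            chosen.extend(pool[i] for i in idx)

    neg_by_protein: dict[str, set] = {}
    for pid, i in chosen:
        neg_by_protein.setdefault(pid, set()).add(i)

    out = {}
    for pid, seq, pos in proteins:
        negs = neg_by_protein.get(pid, set())
        labeled = sorted(pos) + sorted(negs)
        idx = np.array(sorted(labeled), dtype=np.intp)
        labels = np.array([1 if i in pos else 0 for i in idx], dtype=np.intp)
        out[pid] = SiteSet(protein_id=pid, site_indices=idx, labels=labels)
    return out


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def split_random(ids: Sequence[str], n_train: int, seed: int) -> tuple[list, list]:
    """Seed-reproducible disjoint exhaustive protein-level partition."""
    ids = list(ids)
    if not 0 < n_train < len(ids):
        raise ValueError(f"n_train={n_train} out of range for {len(ids)} proteins")
    order = np.random.default_rng(seed).permutation(len(ids))
    train = [ids[i] for i in order[:n_train]]
    test = [ids[i] for i in order[n_train:]]
    return train, test


def split_by_family(ids: Sequence[str], families: dict[str, str],
                    n_train: int) -> tuple[list, list]:
    """Family-disjoint split: larger families fill the training set first.

    Families are sorted by member count descending (name-lexicographic tie
    break) and assigned to training greedily without overshooting n_train;
    everything else is test.  Train and test never share a family.
    """
    missing = [pid for pid in ids if pid not in families]
    if missing:
        raise ValueError(f"missing family labels for: {missing}")
    members: dict[str, list[str]] = {}
    for pid in ids:
        members.setdefault(families[pid], []).append(pid)
    ordered = sorted(members, key=lambda fam: (-len(members[fam]), fam))
    train: list[str] = []
    test: list[str] = []
    for fam in ordered:
        if len(train) + len(members[fam]) <= n_train:
            train.extend(members[fam])
        else:
            test.extend(members[fam])
    return train, test


def split_by_plddt(plddt_means: dict[str, float]) -> tuple[list, list]:
    """Even split by mean structure confidence: upper half high, lower half low.

    Ties (and the median protein when the count is odd) go to the high
    group; ordering within ties is by protein id for determinism.
    """
    missing = [pid for pid, v in plddt_means.items() if v is None or not np.isfinite(v)]
    if missing:
        raise ValueError(f"missing pLDDT means for: {missing}")
    ranked = sorted(plddt_means, key=lambda pid: (-plddt_means[pid], pid))
    cut = (len(ranked) + 1) // 2
    return ranked[:cut], ranked[cut:]


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    params: dict[str, Tensor]
    config: ModelConfig
    loss_log: list
    val_f1_log: list
    best_epoch: int


def _labeled_sites(ex: ProteinExample) -> tuple[np.ndarray, np.ndarray]:
    mask = ex.site_set.labels != UNKNOWN_LABEL
    return ex.site_set.site_indices[mask], ex.site_set.labels[mask]


def train(examples: Sequence[ProteinExample], config: ModelConfig,
          epochs: int = DEFAULT_EPOCHS, lr: float = DEFAULT_LR, seed: int = 0,
          val_fraction: float = DEFAULT_VAL_FRACTION,
          feature_noise: float = DEFAULT_FEATURE_NOISE,
          embedding_noise: float = DEFAULT_EMBEDDING_NOISE) -> TrainResult:
    """Train on balanced site sets, one protein graph per optimizer step.

    The initial learning rate is halved four times over the run.  During
    training, small Gaussian jitter is added to the feature and embedding
    inputs each step (``feature_noise`` / ``embedding_noise``, both
    disableable with 0); with one protein per optimizer step this input
    augmentation is what keeps the over-parameterized branches from
    memorizing individual residues instead of learning their context.

    A seeded ``val_fraction`` carve-out of the training proteins selects
    the best checkpoint by validation F1; with no carve-out the final
    parameters win.  All randomness (init, shuffling, carve-out, jitter)
    derives from ``config.seed`` and ``seed``, so fixed seeds reproduce
    the run bitwise.
    """
    examples = [ex for ex in examples if _labeled_sites(ex)[0].size > 0]
    if not examples:
        raise ValueError("no training examples with labeled sites")

    rng = np.random.default_rng(seed)
    n_val = int(round(val_fraction * len(examples)))
    order = rng.permutation(len(examples))
    val_set = [examples[i] for i in order[:n_val]]
    train_set = [examples[i] for i in order[n_val:]] or list(examples)

    emb_dim = examples[0].embeddings.shape[1]
    feat_dim = examples[0].features.shape[1]
    params = init_params(config, feature_dim=feat_dim, emb_dim=emb_dim)
    optimizer = Adam(params, lr=lr)
    drop_rng = np.random.default_rng(seed + 1) if config.dropout > 0 else None

    loss_log: list[float] = []
    val_f1_log: list[float] = []
    best_f1, best_epoch, best_params = -1.0, epochs - 1, None

    decay_every = max(1, epochs // LR_DECAY_STEPS)
    for epoch in range(epochs):
        optimizer.lr = lr * 0.5 ** (epoch // decay_every)
        epoch_losses = []
        for i in rng.permutation(len(train_set)):
            ex = train_set[i]
            sites, labels = _labeled_sites(ex)
            feats, emb = ex.features, ex.embeddings
            if feature_noise > 0:
                feats = feats + feature_noise * rng.standard_normal(feats.shape)
            if embedding_noise > 0:
                emb = emb + embedding_noise * rng.standard_normal(emb.shape)
            logits = forward_logits(feats, ex.graph, emb, sites,
                                    params, config, train_rng=drop_rng)
            loss = ad.bce_with_logits(logits, labels[:, None].astype(np.float64))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, protein {ex.protein_id}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        loss_log.append(float(np.mean(epoch_losses)))

        if val_set:
            report = evaluate(predict(val_set, params, config),
                              [ex.site_set for ex in val_set])
            val_f1_log.append(report.f1)
            if report.f1 > best_f1:
                best_f1, best_epoch = report.f1, epoch
                best_params = {k: Tensor(p.data.copy(), requires_grad=True)
                               for k, p in params.items()}

    if best_params is not None:
        params = best_params
    return TrainResult(params=params, config=config, loss_log=loss_log,
                       val_f1_log=val_f1_log, best_epoch=best_epoch)


def predict(examples: Sequence[ProteinExample], params: dict[str, Tensor],
            config: ModelConfig) -> list[PredictionResult]:
    out = []
    for ex in examples:
        sites, _ = _labeled_sites(ex)
        site_set = SiteSet(protein_id=ex.protein_id, site_indices=sites,
                           labels=np.zeros(len(sites), dtype=np.intp))
        out.append(forward(ex.features, ex.graph, ex.embeddings, site_set,
                           params, config))
    return out


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(predictions: Sequence[PredictionResult],
             truths: Sequence[SiteSet]) -> MetricsReport:
    """Micro-averaged confusion counts pooled over all proteins."""
    truth_by_id = {t.protein_id: t for t in truths}
    tp = tn = fp = fn = 0
    for pred in predictions:
        if pred.protein_id not in truth_by_id:
            raise ValueError(f"no truth labels for protein {pred.protein_id}")
        truth = truth_by_id[pred.protein_id]
        label_of = dict(zip(truth.site_indices.tolist(), truth.labels.tolist()))
        for idx, call in zip(pred.site_indices.tolist(), pred.calls.tolist()):
            if idx not in label_of:
                raise ValueError(
                    f"{pred.protein_id}: predicted site {idx} absent from truth")
            y = label_of[idx]
            if y == UNKNOWN_LABEL:
                continue
            if y == 1 and call == 1:
                tp += 1
            elif y == 1:
                fn += 1
            elif call == 1:
                fp += 1
            else:
                tn += 1
    return MetricsReport(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> MetricsReport:
    return MetricsReport(tp=tp, tn=tn, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

def run_ablation_suite(train_examples: Sequence[ProteinExample],
                       test_examples: Sequence[ProteinExample],
                       configs: dict[str, ModelConfig],
                       epochs: int = DEFAULT_EPOCHS, lr: float = DEFAULT_LR,
                       seed: int = 0) -> pd.DataFrame:
    """Train and evaluate each configuration on identical data and seeds."""
    rows = []
    for name, config in configs.items():
        result = train(train_examples, config, epochs=epochs, lr=lr, seed=seed)
        report = evaluate(predict(test_examples, result.params, config),
                          [ex.site_set for ex in test_examples])
        rows.append({"config": name, **report.as_dict()})
        logger.info("ablation %s: acc=%.4f pre=%.4f sn=%.4f f1=%.4f",
                    name, report.acc, report.pre, report.sn, report.f1)
    return pd.DataFrame(rows).set_index("config")
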