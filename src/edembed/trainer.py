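"""Training loops: self-supervised pretraining with alternating adversarial
updates, outcome finetuning with the FL_C head, AUROC evaluation, and the
ablation harness (no-pretrain / DIM-only / SimCLR-only / both).

The pretraining step follows the alternating GAN schedule: per minibatch,
one discriminator update (the Deep-InfoMax scorer β_D and the linear domain
discriminator L_DD, on detached embeddings) followed by one encoder update
minimizing DIM NCE + γ·(prior generator term) + SimCLR between two
augmented views. Everything is seeded and single-threaded, so identical
configurations yield bit-identical metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ehr import CohortStats, Visit, impute_and_perturb, select_history
from .losses import (LinearDomainDiscriminator, PretrainLossParts, dim_nce_loss,
                     prior_adversarial_losses, simclr_loss)
from .model import DimDiscriminator, DiseaseEncoder, ModelConfig, augment
from .nn import MLP, Adam, Tensor
from .text import TextEncoder, history_mean, padding_feature

__all__ = [
    "TrainConfig",
    "FeatureSet",
    "build_features",
    "pretrain",
    "embed_dataset",
    "finetune",
    "FinetunedClassifier",
    "evaluate_auroc",
    "run_ablation",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Optimization settings. Full-scale defaults: Adam at learning rate
    1e-4 with minibatch 1024 and γ=0.1; the tests use the desk-scale
    ``small`` preset (batch 64)."""

    learning_rate: float = 1e-4
    batch_size: int = 1024
    epochs: int = 10
    seed: int = 0
    gamma: float = 0.1
    temperature: float = 0.5
    disc_steps_per_gen_step: int = 1
    dim_negatives: int | None = None  # None = all B(B-1) mismatched pairs
    use_dim: bool = True
    use_simclr: bool = True
    use_pretrain: bool = True
    finetune_epochs: int = 30
    finetune_lr: float | None = None   # None: reuse learning_rate
    head_warmup_epochs: int = 0        # head-only epochs before end-to-end
    patience: int = 5
    freeze_encoder: bool = False

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning rate and batch size must be positive")

    @classmethod
    def small(cls, **overrides) -> "TrainConfig":
        kwargs = dict(batch_size=64, learning_rate=1e-3)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class FeatureSet:
    """Model-ready arrays for a cohort: standardized structural vectors,
    text features, history-validity bits, and the training statistics the
    standardization used."""

    visit_ids: list[str]
    s_std: np.ndarray        # (n, 15) imputed & standardized structural data
    cc_feat: np.ndarray      # (n, d_text)
    hx_feat: np.ndarray      # (n, d_text) mean history feature (zeros if none)
    hx_valid: np.ndarray     # (n,) {0,1}
    stats: CohortStats

    def __len__(self) -> int:
        return len(self.visit_ids)

    def subset(self, idx) -> "FeatureSet":
        idx = np.asarray(idx)
        return FeatureSet(
            visit_ids=[self.visit_ids[i] for i in idx],
            s_std=self.s_std[idx], cc_feat=self.cc_feat[idx],
            hx_feat=self.hx_feat[idx], hx_valid=self.hx_valid[idx],
            stats=self.stats,
        )


def build_features(visits: list[Visit], stats: CohortStats,
                   text_encoder: TextEncoder) -> FeatureSet:
    """Impute missing vitals with training means, standardize per field
    using training statistics, encode chief complaints, and average each
    visit's pre-triage history texts.

    Standardizing S puts every field's augmentation noise on the same
    scale: noise_fraction × (field SD) on the raw scale is noise_fraction ×
    1 on the standardized scale.
    """
    mean, sd = stats.mean_vector(), stats.sd_vector()
    sd = np.where(sd > 0, sd, 1.0)
    pad = padding_feature(text_encoder.d_text)
    s_rows, cc_rows, hx_rows, hx_bits = [], [], [], []
    for visit in visits:
        s = impute_and_perturb(visit.vitals, stats, noise_fraction=0.0)
        s_rows.append((s - mean) / sd)
        cc_rows.append(text_encoder.encode(visit.chief_complaint, kind="CC").vector)
        texts = select_history(visit.history_texts, visit.triage_time)
        feats = [text_encoder.encode(t, kind="HX") for t in texts]
        hx, valid = history_mean(feats, pad)
        hx_rows.append(hx.vector)
        hx_bits.append(valid)
    return FeatureSet(
        visit_ids=[v.visit_id for v in visits],
        s_std=np.asarray(s_rows), cc_feat=np.asarray(cc_rows),
        hx_feat=np.asarray(hx_rows), hx_valid=np.asarray(hx_bits, dtype=int),
        stats=stats,
    )


def _check_unique_rows(features: FeatureSet) -> None:
    """Each visit in a contrastive batch is assumed unique; duplicated model
    inputs would make false negatives. Warn if the assumption fails."""
    import warnings

    key = np.column_stack([features.s_std, features.cc_feat[:, :8]])
    uniq = np.unique(np.round(key, 9), axis=0)
    if len(uniq) < len(key):
        warnings.warn("duplicate model inputs in cohort; contrastive batches "
                      "may contain false negatives", stacklevel=3)


@dataclass
class PretrainResult:
    encoder: DiseaseEncoder
    discriminator: DimDiscriminator
    domain_discriminator: LinearDomainDiscriminator
    metrics: pd.DataFrame


def _dim_pairs(b: int, k: int | None, rng: np.random.Generator):
    anchors = np.arange(b)
    if k is None or k >= b - 1:
        ii, jj = np.meshgrid(anchors, anchors, indexing="ij")
        return ii.ravel(), jj.ravel()
    neg_i, neg_j = [], []
    for i in anchors:
        offs = rng.choice(b - 1, size=k, replace=False) + 1
        neg_i.extend([i] * k)
        neg_j.extend((i + offs) % b)
    ii = np.concatenate([anchors, np.array(neg_i)])
    jj = np.concatenate([anchors, np.array(neg_j)])
    return ii, jj


def _dim_bce(scores: Tensor, match: np.ndarray) -> Tensor:
    t = Tensor(match.astype(float))
    return -(t * scores.log() + (1.0 - t) * (1.0 - scores).log()).mean()


def pretrain(features: FeatureSet, encoder: DiseaseEncoder,
             config: TrainConfig, metrics_path=None) -> PretrainResult:
    """Self-supervised pretraining of the disease encoder.

    Per batch: two augmented views are built and embedded; the DIM
    discriminator and the linear domain discriminator take one update on
    detached embeddings; then the encoder takes one update on
    dim_nce + γ·prior_gen + simclr. A fresh Uniform[-1,1]^d prior batch is
    drawn each step. Loss parts are logged per step.
    """
    _check_unique_rows(features)
    mcfg = encoder.config
    ss = np.random.SeedSequence(config.seed)
    rng_order, rng_aug, rng_prior, rng_pairs, rng_init = \
        [np.random.default_rng(s) for s in ss.spawn(5)]
    disc = DimDiscriminator(mcfg, rng_init)
    ldd = LinearDomainDiscriminator(mcfg.d_hidden, rng_init)
    enc_opt = Adam(encoder.parameters(), lr=config.learning_rate)
    disc_opt = Adam(disc.parameters() + ldd.parameters(), lr=config.learning_rate)
    sd_ones = np.ones(mcfg.d_struct)
    rows = []
    step = 0
    n = len(features)
    for _epoch in range(config.epochs if config.use_pretrain else 0):
        order = rng_order.permutation(n)
        for lo in range(0, n - 1, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            if len(idx) < 2:
                continue
            batch = features.subset(idx)
            if not (config.use_dim or config.use_simclr):
                continue  # no objective: parameters must stay untouched
            s1, hxv1 = augment(batch.s_std, batch.hx_valid, sd_ones, mcfg, rng_aug)
            s2, hxv2 = augment(batch.s_std, batch.hx_valid, sd_ones, mcfg, rng_aug)

            m_s1 = encoder.project_structural(s1)
            m_cc = encoder.project_text(batch.cc_feat)
            m_hx = encoder.project_text(batch.hx_feat)
            eps1 = encoder.embed(encoder.assemble_input(m_s1, m_cc, m_hx, hxv1))
            m_s2 = encoder.project_structural(s2)
            eps2 = encoder.embed(encoder.assemble_input(m_s2, m_cc, m_hx, hxv2))

            b = len(idx)
            pair_i, pair_j = _dim_pairs(b, config.dim_negatives, rng_pairs)
            match = (pair_i == pair_j)
            prior = rng_prior.uniform(-1.0, 1.0, size=(b, mcfg.d_hidden))

            dim_nce_val = prior_gen_val = prior_disc_val = simclr_val = 0.0
            # ---- discriminator step (β_D and L_DD, detached ε) ----------
            if config.use_dim:
                eps_d = eps1.detach()
                m_s_d, m_cc_d, m_hx_d = m_s1.detach(), m_cc.detach(), m_hx.detach()
                for _ in range(config.disc_steps_per_gen_step):
                    scores = disc.score(eps_d[pair_i], m_s_d[pair_j], m_cc_d[pair_j],
                                        m_hx_d[pair_j], hxv1[pair_j])
                    d_loss, _g = prior_adversarial_losses(eps_d, prior, ldd)
                    disc_total = _dim_bce(scores, match) + d_loss
                    disc_opt.zero_grad()
                    disc_total.backward()
                    disc_opt.step()
                    prior_disc_val = float(d_loss.item())

            # ---- encoder step (scores recomputed with updated β_D) ------
            loss_terms = []
            if config.use_dim:
                scores = disc.score(eps1[pair_i], m_s1[pair_j], m_cc[pair_j],
                                    m_hx[pair_j], hxv1[pair_j])
                dim_term = _dim_bce(scores, match)
                _d, gen_loss = prior_adversarial_losses(eps1, prior, ldd)
                loss_terms += [dim_term, config.gamma * gen_loss]
                dim_nce_val, prior_gen_val = float(dim_term.item()), float(gen_loss.item())
            if config.use_simclr:
                sim_term = simclr_loss(eps1, eps2, config.temperature)
                loss_terms.append(sim_term)
                simclr_val = float(sim_term.item())
            total = loss_terms[0]
            for t in loss_terms[1:]:
                total = total + t
            if not np.isfinite(total.item()):
                raise RuntimeError(f"NaN/inf pretraining loss at step {step}: "
                                   f"dim={dim_nce_val} prior={prior_gen_val} simclr={simclr_val}")
            encoder.zero_grad()
            disc.zero_grad()
            ldd.zero_grad()
            total.backward()
            enc_opt.step()  # encoder parameters only
            encoder.zero_grad(); disc.zero_grad(); ldd.zero_grad()

            parts = PretrainLossParts(dim_nce=dim_nce_val, prior_gen=prior_gen_val,
                                      prior_disc=prior_disc_val, simclr=simclr_val,
                                      gamma=config.gamma)
            rows.append({"step": step, "dim_nce": parts.dim_nce,
                         "prior_gen": parts.prior_gen, "prior_disc": parts.prior_disc,
                         "simclr": parts.simclr, "total": parts.total})
            step += 1
    metrics = pd.DataFrame(rows, columns=["step", "dim_nce", "prior_gen",
                                          "prior_disc", "simclr", "total"])
    if metrics_path is not None:
        metrics.to_csv(metrics_path, index=False)
    return PretrainResult(encoder=encoder, discriminator=disc,
                          domain_discriminator=ldd, metrics=metrics)


def embed_dataset(encoder: DiseaseEncoder, features: FeatureSet,
                  batch_size: int = 256) -> np.ndarray:
    """Deterministic (no-augmentation) embeddings for every visit."""
    out = []
    for lo in range(0, len(features), batch_size):
        batch = features.subset(np.arange(lo, min(lo + batch_size, len(features))))
        eps = encoder(batch.s_std, batch.cc_feat, batch.hx_feat, batch.hx_valid)
        out.append(eps.data)
    return np.concatenate(out, axis=0)


class FinetunedClassifier:
    """Encoder + FL_C head scoring the critical-care outcome."""

    def __init__(self, encoder: DiseaseEncoder, head: MLP):
        self.encoder = encoder
        self.head = head

    def logits(self, features: FeatureSet, batch_size: int = 256) -> np.ndarray:
        out = []
        for lo in range(0, len(features), batch_size):
            batch = features.subset(np.arange(lo, min(lo + batch_size, len(features))))
            eps = self.encoder(batch.s_std, batch.cc_feat, batch.hx_feat, batch.hx_valid)
            out.append(self.head(eps).data.reshape(-1))
        return np.concatenate(out)

    def predict_scores(self, features: FeatureSet) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.logits(features)))


def _weighted_bce_with_logits(logits: Tensor, y: np.ndarray, pos_weight: float) -> Tensor:
    yt = Tensor(y.astype(float))
    w = Tensor(np.where(y == 1, pos_weight, 1.0))
    abs_l = logits.relu() + (-logits).relu()
    loss = logits.relu() - logits * yt + ((-abs_l).exp() + 1.0).log()
    return (w * loss).sum() / w.data.sum()


def finetune(encoder: DiseaseEncoder, features: FeatureSet, labels: np.ndarray,
             config: TrainConfig,
             val_features: FeatureSet | None = None,
             val_labels: np.ndarray | None = None) -> FinetunedClassifier:
    """Attach the FL_C head and train on the binary outcome.

    Optionally warms the head up with the encoder frozen
    (``head_warmup_epochs``), then trains end-to-end at ``finetune_lr``
    (the encoder stays frozen throughout under ``config.freeze_encoder``).
    The warmup lets a pretrained representation be exploited before
    end-to-end updates start moving it. Class imbalance is handled by
    weighting the positive class with n_neg/n_pos in the BCE; early
    stopping monitors validation AUROC when a validation set is given.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("DEGENERATE_LABELS: need both outcome classes to finetune")
    ss = np.random.SeedSequence(config.seed + 1)
    rng_init, rng_order = [np.random.default_rng(s) for s in ss.spawn(2)]
    head = MLP([encoder.config.d_hidden, 64, 1], rng_init)
    clf = FinetunedClassifier(encoder, head)
    pos_weight = float((labels == 0).sum()) / float((labels == 1).sum())
    n = len(features)

    def run_epochs(n_epochs, params, lr):
        opt = Adam(params, lr=lr)
        for _epoch in range(n_epochs):
            order = rng_order.permutation(n)
            for lo in range(0, n, config.batch_size):
                idx = order[lo:lo + config.batch_size]
                batch = features.subset(idx)
                eps = encoder(batch.s_std, batch.cc_feat, batch.hx_feat, batch.hx_valid)
                logits = head(eps).reshape(-1)
                loss = _weighted_bce_with_logits(logits, labels[idx], pos_weight)
                encoder.zero_grad(); head.zero_grad()
                loss.backward()
                opt.step()
            yield None

    if config.head_warmup_epochs > 0:
        for _ in run_epochs(config.head_warmup_epochs, head.parameters(),
                            config.learning_rate):
            pass
    params = head.parameters() + ([] if config.freeze_encoder else encoder.parameters())
    lr = config.finetune_lr if config.finetune_lr is not None else config.learning_rate
    best_auc, best_state, stale = -np.inf, None, 0
    for _ in run_epochs(config.finetune_epochs, params, lr):
        if val_features is not None and val_labels is not None:
            auc = evaluate_auroc(clf.logits(val_features), val_labels)
            if auc > best_auc + 1e-6:
                best_auc, stale = auc, 0
                best_state = (encoder.state_dict(), head.state_dict())
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if best_state is not None:
        encoder.load_state_dict(best_state[0])
        head.load_state_dict(best_state[1])
    return clf


def evaluate_auroc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation
    with midranks for ties: the probability that a random positive outranks
    a random negative."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


ABLATIONS = {
    "both": dict(use_pretrain=True, use_dim=True, use_simclr=True),
    "dim_only": dict(use_pretrain=True, use_dim=True, use_simclr=False),
    "simclr_only": dict(use_pretrain=True, use_dim=False, use_simclr=True),
    "no_pretrain": dict(use_pretrain=False, use_dim=False, use_simclr=False),
}


def _label_subsample(train_labels: np.ndarray, budget: int,
                     rng: np.random.Generator) -> np.ndarray:
    pos = np.flatnonzero(train_labels == 1)
    neg = np.flatnonzero(train_labels == 0)
    n_pos = max(2, int(round(budget * len(pos) / len(train_labels))))
    n_pos = min(n_pos, len(pos))
    return np.concatenate([rng.choice(pos, size=n_pos, replace=False),
                           rng.choice(neg, size=budget - n_pos, replace=False)])


def run_ablation(train_features: FeatureSet, train_labels: np.ndarray,
                 test_features: FeatureSet, test_labels: np.ndarray,
                 model_config: ModelConfig, base_config: TrainConfig,
                 seeds: list[int],
                 label_budget: int | None = None,
                 label_draws: int = 1) -> pd.DataFrame:
    """Pretrain/finetune each ablation arm for each seed and return test
    AUROCs (rows: seed × arm, averaged over ``label_draws`` stratified
    label subsamples of size ``label_budget``). Pretraining is done once
    per (seed, arm); only the cheap finetuning is repeated per label draw,
    which averages out the considerable small-label-sample noise."""
    from dataclasses import replace

    rows = []
    for seed in seeds:
        draw_rng = np.random.default_rng(seed + 10_000)
        if label_budget is not None and label_budget < len(train_features):
            picks = [_label_subsample(train_labels, label_budget, draw_rng)
                     for _ in range(label_draws)]
        else:
            picks = [np.arange(len(train_features))]
        for arm, flags in ABLATIONS.items():
            cfg = replace(base_config, seed=seed, **flags)
            encoder = DiseaseEncoder(model_config, np.random.default_rng(seed))
            if cfg.use_pretrain:
                pretrain(train_features, encoder, cfg)
            state = encoder.state_dict()
            aucs = []
            for pick in picks:
                encoder.load_state_dict(state)
                clf = finetune(encoder, train_features.subset(pick),
                               train_labels[pick], cfg)
                aucs.append(evaluate_auroc(clf.logits(test_features), test_labels))
            rows.append({"seed": seed, "arm": arm, "auroc": float(np.mean(aucs))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Checkpointing: one .npz archive holding every parameter plus a JSON header
# with the architecture configuration.

def save_checkpoint(path, encoder: DiseaseEncoder) -> None:
    state = {f"param/{k}": v for k, v in encoder.state_dict().items()}
    state["config_json"] = np.array(json.dumps(encoder.config.to_dict()))
    np.savez(path, **state)


def load_checkpoint(path) -> DiseaseEncoder:
    with np.load(path, allow_pickle=False) as archive:
        config = ModelConfig(**json.loads(str(archive["config_json"])))
        encoder = DiseaseEncoder(config, np.random.default_rng(0))
        encoder.load_state_dict({k[len("param/"):]: archive[k]
                                 for k in archive.files if k.startswith("param/")})
    return encoder
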