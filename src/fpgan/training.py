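"""Training protocols: discriminator pre-training, the two-step
alternating GAN loop, its conditional variant, and fingerprint sampling.

Each GAN epoch is one full pass over the real set in mini-batches.  Per
batch there are exactly two phases: (1) the discriminator updates on a real
batch labeled positive and a freshly generated batch labeled negative while
the generator is frozen; (2) the generator updates through the frozen
discriminator with positive labels on its own samples (the non-saturating
form of the minimax objective).  Freezing is structural — each phase steps
only its own optimizer — and can be audited via parameter checksums.

The conditional variant appends a one-hot class label to the generator's
noise and to the discriminator's fingerprint input, so inactive compounds
can steer sampling toward the active class at generation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import nn
from .dataset import FoldAssignment, LabeledFingerprintSet
from .evaluation import ClassifierMetrics, classifier_metrics
from .fingerprints import BitFingerprint
from .models import (
    ArchitectureSpec,
    DiscriminatorModel,
    GeneratorModel,
    GeneratorSpec,
    build_discriminator,
    build_generator,
)

REAL, FAKE = 1, 0


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyperparameters.

    Defaults follow the published protocol: 100 discriminator pre-training
    epochs, 800 adversarial epochs, batch size 32, learning rates 1e-6 for
    the discriminator and 1e-3 for the generator in the adversarial stage.
    ``pretrain_learning_rate`` governs the standalone discriminator stage,
    whose rate the protocol leaves at the optimizer default.
    """

    d_epochs: int = 100
    gan_epochs: int = 800
    batch_size: int = 32
    d_learning_rate: float = 1e-6
    g_learning_rate: float = 1e-3
    pretrain_learning_rate: float = 1e-3
    l2_coeff: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.d_epochs, self.gan_epochs, self.batch_size) <= 0:
            raise ValueError("epochs and batch size must be positive")
        if min(self.d_learning_rate, self.g_learning_rate,
               self.pretrain_learning_rate) < 0:
            raise ValueError("learning rates must be non-negative")
        if self.l2_coeff < 0:
            raise ValueError("l2_coeff must be non-negative")

    @classmethod
    def demo_scale(cls, seed: int = 0, gan_epochs: int = 200) -> "TrainingConfig":
        """Scaled-down adversarial protocol for desk-size runs.

        Keeps the published batch size and generator rate but trains the
        discriminator from scratch at an optimizer-default-scale rate
        (1e-4): the published 1e-6 assumes a pre-trained discriminator and
        is too slow to move a fresh one within a few hundred epochs.
        """
        return cls(gan_epochs=gan_epochs, d_learning_rate=1e-4,
                   g_learning_rate=1e-3, seed=seed)


@dataclass
class TrainingLog:
    """Per-epoch losses and discriminator accuracy on real-vs-generated."""

    d_loss: list[float] = field(default_factory=list)
    g_loss: list[float] = field(default_factory=list)
    d_accuracy: list[float] = field(default_factory=list)

    def append(self, d_loss: float, g_loss: float, d_acc: float) -> None:
        for v in (d_loss, g_loss, d_acc):
            if not np.isfinite(v):
                raise FloatingPointError("non-finite training statistic")
        self.d_loss.append(d_loss)
        self.g_loss.append(g_loss)
        self.d_accuracy.append(d_acc)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(len(self.d_loss)),
            "d_loss": self.d_loss,
            "g_loss": self.g_loss,
            "d_accuracy": self.d_accuracy,
        })


@dataclass
class PretrainResult:
    fold_metrics: list[ClassifierMetrics]
    model: DiscriminatorModel

    @property
    def mean_auc(self) -> float:
        return float(np.mean([m.auc for m in self.fold_metrics]))

    def means(self) -> dict[str, float]:
        keys = ("auc", "accuracy", "f1", "precision", "recall")
        return {k: float(np.mean([getattr(m, k) for m in self.fold_metrics]))
                for k in keys}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.to_dict() for m in self.fold_metrics])


def _fit_classifier(model: DiscriminatorModel, x: np.ndarray, y: np.ndarray,
                    epochs: int, batch_size: int, lr: float, l2: float,
                    rng: np.random.Generator,
                    progress: Callable[[int], None] | None = None) -> None:
    opt = nn.Adam(model.net, lr=lr, l2=l2)
    n = x.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            logits = model.logits(x[idx], training=True)
            _, dlogits = nn.categorical_cross_entropy(logits, nn.one_hot(y[idx], 2))
            model.net.backward(dlogits)
            opt.step()
        if progress is not None:
            progress(epoch)


def pretrain_discriminator(
    data: LabeledFingerprintSet,
    spec: ArchitectureSpec | str,
    folds: FoldAssignment,
    cfg: TrainingConfig,
    max_folds: int | None = None,
) -> PretrainResult:
    """Cross-validated discriminator training on active/decoy fingerprints.

    For each fold, trains a fresh model on the other k-1 folds and scores
    the held-out fold (AUC, accuracy, F1, precision, recall, confusion).
    ``max_folds`` caps how many folds are evaluated for scaled-down runs;
    the returned model is the one from the last evaluated fold.
    """
    if len(data) != folds.fold.size:
        raise ValueError("fold assignment does not align with the dataset")
    x = data.fingerprints.astype(float)
    y = data.labels
    n_eval = folds.k if max_folds is None else min(max_folds, folds.k)
    metrics: list[ClassifierMetrics] = []
    model: DiscriminatorModel | None = None
    for f in range(n_eval):
        rng = np.random.default_rng(cfg.seed + 1000 * f)
        model = build_discriminator(spec, input_length=data.length,
                                    seed=cfg.seed + f)
        tr, te = folds.train_indices(f), folds.test_indices(f)
        _fit_classifier(model, x[tr], y[tr], cfg.d_epochs, cfg.batch_size,
                        cfg.pretrain_learning_rate, cfg.l2_coeff, rng)
        scores = model.predict_proba(x[te])[:, REAL]
        metrics.append(classifier_metrics(y[te], scores))
    assert model is not None
    return PretrainResult(metrics, model)


class GanTrainer:
    """The two-step alternating loop, exposed step-by-step for auditing."""

    def __init__(self, generator: GeneratorModel,
                 discriminator: DiscriminatorModel,
                 cfg: TrainingConfig, n_classes: int | None = None):
        if (n_classes is not None) != (generator.conditional):
            raise ValueError("generator conditioning must match n_classes")
        self.g = generator
        self.d = discriminator
        self.cfg = cfg
        self.n_classes = n_classes
        self.opt_d = nn.Adam(discriminator.net, lr=cfg.d_learning_rate,
                             l2=cfg.l2_coeff)
        self.opt_g = nn.Adam(generator.net, lr=cfg.g_learning_rate)
        self.rng = np.random.default_rng(cfg.seed)

    def _d_input(self, fps: np.ndarray, labels: np.ndarray | None) -> np.ndarray:
        if self.n_classes is None:
            return fps
        from .models import condition_join
        return condition_join(fps, labels, self.n_classes)

    def discriminator_step(self, real_batch: np.ndarray,
                           real_labels: np.ndarray | None = None
                           ) -> tuple[float, float]:
        """Phase 1: update D on real (positive) vs generated (negative)."""
        m = real_batch.shape[0]
        z = self.g.noise(m, self.rng)
        fake = self.g.generate(z, label=real_labels, training=False)
        x = np.vstack([self._d_input(real_batch.astype(float), real_labels),
                       self._d_input(fake, real_labels)])
        y = np.concatenate([np.full(m, REAL), np.full(m, FAKE)])
        logits = self.d.logits(x, training=True)
        loss, dlogits = nn.categorical_cross_entropy(logits, nn.one_hot(y, 2))
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite discriminator loss")
        self.d.net.backward(dlogits)
        self.opt_d.step()
        acc = float((logits.argmax(axis=1) == y).mean())
        return loss, acc

    def generator_step(self, batch_size: int,
                       labels: np.ndarray | None = None) -> float:
        """Phase 2: update G through the frozen D with positive labels."""
        z = self.g.noise(batch_size, self.rng)
        fake = self.g.generate(z, label=labels, training=True)
        logits = self.d.logits(self._d_input(fake, labels), training=False)
        loss, dlogits = nn.categorical_cross_entropy(
            logits, nn.one_hot(np.full(batch_size, REAL), 2))
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite generator loss")
        dx = self.d.net.backward(dlogits)  # gradients flow; D is not stepped
        if self.n_classes is not None:
            dx = dx[:, : self.g.spec.output_length]
        self.g.net.backward(dx)
        self.opt_g.step()
        return loss

    def _sample_labels(self, pool: np.ndarray, m: int) -> np.ndarray:
        return pool[self.rng.integers(0, pool.size, size=m)]

    def train(self, real: np.ndarray, epochs: int,
              real_labels: np.ndarray | None = None) -> TrainingLog:
        log = TrainingLog()
        n = real.shape[0]
        bs = self.cfg.batch_size
        for epoch in range(epochs):
            order = self.rng.permutation(n)
            d_losses, g_losses, d_accs = [], [], []
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                lab = None if real_labels is None else real_labels[idx]
                try:
                    d_loss, d_acc = self.discriminator_step(real[idx], lab)
                    g_lab = (None if real_labels is None
                             else self._sample_labels(real_labels, len(idx)))
                    g_loss = self.generator_step(len(idx), g_lab)
                except FloatingPointError as err:
                    raise FloatingPointError(
                        f"epoch {epoch}, batch at {start}: {err}") from err
                d_losses.append(d_loss)
                g_losses.append(g_loss)
                d_accs.append(d_acc)
            log.append(float(np.mean(d_losses)), float(np.mean(g_losses)),
                       float(np.mean(d_accs)))
        return log


def train_dcgan(
    real: LabeledFingerprintSet,
    d_spec: ArchitectureSpec | str = "AlexNet",
    g_spec: GeneratorSpec | None = None,
    cfg: TrainingConfig | None = None,
) -> tuple[GeneratorModel, DiscriminatorModel, TrainingLog]:
    """Train the unconditional fingerprint GAN on a set of real actives.

    Every row of ``real`` is treated as a real sample; pass
    ``real.actives()`` to train on the active class only.
    """
    cfg = cfg or TrainingConfig()
    g_spec = g_spec or GeneratorSpec(output_length=real.length)
    if g_spec.condition_dim is not None:
        raise ValueError("use train_cdcgan for a conditional generator")
    g = build_generator(g_spec, seed=cfg.seed, scheme=real.scheme)
    d = build_discriminator(d_spec, input_length=real.length, seed=cfg.seed + 1)
    trainer = GanTrainer(g, d, cfg)
    log = trainer.train(real.fingerprints.astype(float), cfg.gan_epochs)
    return g, d, log


def train_cdcgan(
    data: LabeledFingerprintSet,
    d_spec: ArchitectureSpec | str = "AlexNet",
    g_spec: GeneratorSpec | None = None,
    cfg: TrainingConfig | None = None,
    n_classes: int = 2,
) -> tuple[GeneratorModel, DiscriminatorModel, TrainingLog]:
    """Train the conditional GAN on actives and inactives jointly.

    The class label is appended one-hot to both the generator noise and the
    discriminator input; at sampling time the returned generator takes the
    desired class label.
    """
    cfg = cfg or TrainingConfig()
    if len(np.unique(data.labels)) < 2:
        raise ValueError("conditional training requires both classes")
    g_spec = g_spec or GeneratorSpec(output_length=data.length,
                                     condition_dim=n_classes)
    if g_spec.condition_dim != n_classes:
        raise ValueError("g_spec.condition_dim must equal n_classes")
    g = build_generator(g_spec, seed=cfg.seed, scheme=data.scheme)
    d = build_discriminator(d_spec, input_length=data.length,
                            condition_dim=n_classes, seed=cfg.seed + 1)
    trainer = GanTrainer(g, d, cfg, n_classes=n_classes)
    log = trainer.train(data.fingerprints.astype(float), cfg.gan_epochs,
                        real_labels=data.labels)
    return g, d, log


def sample_fingerprints(
    generator: GeneratorModel,
    n: int,
    seed: int,
    label: int | None = None,
    threshold: float = 0.5,
) -> list[BitFingerprint]:
    """Draw ``n`` fingerprints from a trained generator.

    Noise is seeded, outputs are binarized at ``threshold`` (bit = 1 when
    the continuous output is >= threshold).  A masked generator therefore
    yields fingerprints containing every mask bit for any threshold <= 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[BitFingerprint] = []
    batch = 512
    made = 0
    while made < n:
        m = min(batch, n - made)
        z = generator.noise(m, rng)
        cont = generator.generate(z, label=label, training=False)
        bits = (cont >= threshold).astype(np.uint8)
        for row in bits:
            out.append(BitFingerprint(row, generator.scheme,
                                      f"gen_{made:05d}"))
            made += 1
    return out
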