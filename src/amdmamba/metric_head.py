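"""Stage-1 cosine-prototype classifier.

Severity is graded on a 1..12 step scale per eye (>= 10 is late disease).
Classification operates on grouped phenotype classes; the default grouping
is four classes: no (1), early (2-5), intermediate (6-9), late (10-12).
A learnable prototype matrix ``g`` holds one row per class; the logit for
class i is the cosine similarity between the pooled backbone latent f4 and
g_i, and training minimizes the softmax cross-entropy over those cosine
logits.  No temperature is applied by default (logits live in [-1, 1]); an
optional temperature divides the logits when configured.
"""

from __future__ import annotations

import numpy as np

from .nn import Module, Parameter, Tensor

__all__ = [
    "score_to_class",
    "n_classes",
    "PrototypeClassifier",
    "cosine_logits_np",
    "metric_ce_loss_np",
    "soft_label_weights_np",
]

_FOUR_CLASS_EDGES = {1: 0, 2: 1, 3: 1, 4: 1, 5: 1, 6: 2, 7: 2, 8: 2, 9: 2, 10: 3, 11: 3, 12: 3}


def score_to_class(score, grouping: str = "four_class") -> np.ndarray:
    """Map raw 1..12 severity scores to 0-based class indices."""
    arr = np.asarray(score)
    if np.any((arr < 1) | (arr > 12)):
        raise ValueError("severity scores must lie in 1..12")
    if grouping == "four_class":
        return np.vectorize(_FOUR_CLASS_EDGES.get)(arr)
    if grouping == "twelve_class":
        return arr - 1
    if grouping == "binary":
        # non-late (1-9) vs late (10-12)
        return (arr >= 10).astype(int)
    raise ValueError(f"unknown grouping {grouping!r}")


def n_classes(grouping: str) -> int:
    return {"four_class": 4, "twelve_class": 12, "binary": 2}[grouping]


def cosine_logits_np(f4: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    """Cosine similarity between each row of f4 and each prototype row."""
    f4 = np.atleast_2d(np.asarray(f4, dtype=float))
    g = np.asarray(prototypes, dtype=float)
    fn = np.linalg.norm(f4, axis=-1)
    gn = np.linalg.norm(g, axis=-1)
    if np.any(fn == 0):
        raise ValueError("cosine similarity undefined for zero-norm feature vector")
    if np.any(gn == 0):
        raise ValueError("cosine similarity undefined for zero-norm prototype")
    return (f4 / fn[:, None]) @ (g / gn[:, None]).T


def metric_ce_loss_np(logits: np.ndarray, label: int) -> float:
    logits = np.asarray(logits, dtype=float)
    m = logits.max()
    return float(-(logits[label] - m) + np.log(np.exp(logits - m).sum()))


def soft_label_weights_np(logits: np.ndarray) -> np.ndarray:
    logits = np.asarray(logits, dtype=float)
    z = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return z / z.sum(axis=-1, keepdims=True)


class PrototypeClassifier(Module):
    """Learnable class prototypes with a cosine decision rule.

    Prototypes are initialized as random unit-norm rows from a dedicated
    seed.  Argmax ties break to the lowest class index (np.argmax default).
    """

    def __init__(self, n_classes_: int, dim: int, init_seed: int = 0,
                 temperature: float | None = None):
        if n_classes_ < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(init_seed)
        g = rng.standard_normal((n_classes_, dim))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        self.prototypes = Parameter(g)
        self.temperature = temperature

    @property
    def n_classes(self) -> int:
        return self.prototypes.shape[0]

    def cosine_logits(self, f4: Tensor) -> Tensor:
        """Differentiable cosine logits for a batch of latents (B, d)."""
        f4 = f4 if isinstance(f4, Tensor) else Tensor(f4)
        fn = np.linalg.norm(f4.data, axis=-1)
        gn = np.linalg.norm(self.prototypes.data, axis=-1)
        if np.any(fn == 0) or np.any(gn == 0):
            raise ValueError("cosine similarity undefined for zero-norm vector")
        f_inv = (f4 * f4).sum(axis=-1, keepdims=True).sqrt()
        g_inv = (self.prototypes * self.prototypes).sum(axis=-1, keepdims=True).sqrt()
        logits = (f4 / f_inv) @ (self.prototypes / g_inv).transpose(1, 0)
        if self.temperature is not None:
            logits = logits * (1.0 / self.temperature)
        return logits

    def loss(self, f4: Tensor, labels: np.ndarray, logits: Tensor | None = None) -> Tensor:
        """Mean cross-entropy over cosine logits (the Stage-1 objective)."""
        if logits is None:
            logits = self.cosine_logits(f4)
        labels = np.asarray(labels, dtype=int)
        B = logits.shape[0]
        shift = Tensor(logits.data.max(axis=-1, keepdims=True))  # constant
        z = (logits - shift).exp()
        log_den = z.sum(axis=-1, keepdims=True).log() + shift
        picked = (logits * _one_hot(labels, logits.shape[1])).sum(axis=-1, keepdims=True)
        return (log_den - picked).mean()

    def predict(self, f4) -> np.ndarray:
        data = f4.data if isinstance(f4, Tensor) else np.asarray(f4, dtype=float)
        logits = cosine_logits_np(data, self.prototypes.data)
        return np.argmax(logits, axis=-1)

    def soft_weights(self, f4) -> np.ndarray:
        data = f4.data if isinstance(f4, Tensor) else np.asarray(f4, dtype=float)
        logits = cosine_logits_np(data, self.prototypes.data)
        if self.temperature is not None:
            logits = logits / self.temperature
        return soft_label_weights_np(logits)


def _one_hot(labels: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((labels.shape[0], n))
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out
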