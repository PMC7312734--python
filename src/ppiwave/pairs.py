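"""Pair feature construction and forward/backward augmentation.

A pair record concatenates the two 600-value protein descriptors in
(A, B) order into a 1200-value feature with a one-hot label:
(1, 0) = interacting, (0, 1) = non-interacting.

Because the classifier consumes an ordered concatenation while the
underlying relation is symmetric, every *training* pair (A + B, label)
is augmented with its swapped copy (B + A, label), exactly doubling the
training set.  Test splits are never augmented; attempting to raises
:class:`~ppiwave.exceptions.LeakageError`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ppiwave.exceptions import InvalidInputError, LeakageError
from ppiwave.wavelets import N_FEATURES, ProteinFeatureVector

INTERACTING = (1, 0)
NON_INTERACTING = (0, 1)
_VALID_LABELS = (INTERACTING, NON_INTERACTING)


def label_from_int(label: int) -> tuple[int, int]:
    """Map 1/0 class convention to the one-hot pair."""
    if label == 1:
        return INTERACTING
    if label == 0:
        return NON_INTERACTING
    raise InvalidInputError(f"label must be 0 or 1, got {label!r}")


@dataclass(frozen=True)
class PairRecord:
    """A labelled protein pair by id."""

    id_a: str
    id_b: str
    label: tuple[int, int]

    def __post_init__(self):
        if tuple(self.label) not in _VALID_LABELS:
            raise InvalidInputError(
                f"label must be (1,0) or (0,1), got {self.label!r}"
            )
        object.__setattr__(self, "label", tuple(self.label))

    @property
    def interacting(self) -> bool:
        return self.label == INTERACTING


@dataclass(frozen=True)
class PairFeature:
    """1200-value concatenated pair feature with one-hot label."""

    values: np.ndarray  # a1..a600, b1..b600
    label: tuple[int, int]
    id_a: str = ""
    id_b: str = ""
    is_training: bool = True
    origin: str = "fwd"  # fwd | bwd, for audit

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (2 * N_FEATURES,):
            raise InvalidInputError(
                f"pair feature must have {2 * N_FEATURES} values, got {v.shape}"
            )
        if tuple(self.label) not in _VALID_LABELS:
            raise InvalidInputError(
                f"label must be (1,0) or (0,1), got {self.label!r}"
            )
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "label", tuple(self.label))

    @property
    def interacting(self) -> bool:
        return self.label == INTERACTING

    def swapped(self) -> "PairFeature":
        """The (B + A)-ordered copy, same label."""
        v = np.concatenate([self.values[N_FEATURES:], self.values[:N_FEATURES]])
        return replace(self, values=v, id_a=self.id_b, id_b=self.id_a,
                       origin="bwd" if self.origin == "fwd" else "fwd")


def build_pair_feature(
    fa: ProteinFeatureVector,
    fb: ProteinFeatureVector,
    label: tuple[int, int],
    *,
    is_training: bool = True,
) -> PairFeature:
    """Concatenate two protein descriptors in (A, B) order."""
    if fa.values.shape != (N_FEATURES,) or fb.values.shape != (N_FEATURES,):
        raise InvalidInputError("both protein descriptors must have length 600")
    return PairFeature(
        values=np.concatenate([fa.values, fb.values]),
        label=label,
        id_a=fa.protein_id,
        id_b=fb.protein_id,
        is_training=is_training,
    )


def augment_forward_backward(training_pairs: list[PairFeature]) -> list[PairFeature]:
    """Double a training split with swapped copies.

    Every input (A + B, label) is kept and its swap (B + A, label) is
    appended.  No deduplication: self-pairs and pre-existing reversed
    pairs still contribute their copy, so the output length is exactly
    2 x the input length.  Records flagged as test data are rejected.
    """
    for p in training_pairs:
        if not p.is_training:
            raise LeakageError(
                f"refusing to augment test-split pair ({p.id_a!r}, {p.id_b!r})"
            )
    return list(training_pairs) + [p.swapped() for p in training_pairs]


def pair_matrix(pairs: list[PairFeature]) -> tuple[np.ndarray, np.ndarray]:
    """Stack pair features into (n, 1200) X and (n, 2) one-hot Y arrays."""
    if not pairs:
        raise InvalidInputError("empty pair list")
    X = np.stack([p.values for p in pairs])
    Y = np.array([p.label for p in pairs], dtype=float)
    return X, Y
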