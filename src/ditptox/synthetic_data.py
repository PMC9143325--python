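"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates the shape of a small imbalanced QSAR dataset: a
binary fragment matrix in which a handful of planted "alert" bits are
enriched in the toxicant class at configurable rates, a continuous
descriptor block with configurable class mean-shifts (unit-variance
Gaussians), class imbalance matching the study's 93/225 positive fraction
by default, and optional label noise. Ground truth (planted alert indices
and their theoretical enrichment frequencies) is returned alongside the
data so parameter-recovery tests are one-liners.

A small hand-validated SMILES fixture is also provided for featurizer
smoke tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import LabeledDataset, MoleculeRecord
from .featurization import FeatureBlock

__all__ = ["SyntheticSpec", "generate_feature_dataset", "generate_smiles_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters for the generator.

    positive_fraction defaults to 0.41 (the 93-toxicant / 225-compound
    imbalance), so class-balancing code paths are exercised by default.
    planted_alerts entries are (bit index, P(bit=1 | toxicant),
    P(bit=1 | non-toxicant)).
    """

    n_molecules: int = 225
    positive_fraction: float = 0.41
    n_fragment_bits: int = 200
    planted_alerts: tuple = ((0, 0.8, 0.1), (1, 0.8, 0.1), (2, 0.8, 0.1))
    background_bit_probability: float = 0.15
    n_descriptors: int = 10
    descriptor_effect_sizes: tuple | float = 1.5
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 10:
            raise ValueError("n_molecules must be at least 10")
        for p in (self.positive_fraction, self.background_bit_probability,
                  self.label_noise):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        idx = [a[0] for a in self.planted_alerts]
        if len(set(idx)) != len(idx) or any(
            not 0 <= i < self.n_fragment_bits for i in idx
        ):
            raise ValueError(
                "planted alert indices must be distinct and < n_fragment_bits"
            )
        for _, p_pos, p_neg in self.planted_alerts:
            if not (0 <= p_pos <= 1 and 0 <= p_neg <= 1):
                raise ValueError("planted alert probabilities must lie in [0, 1]")

    @property
    def effect_sizes(self) -> np.ndarray:
        e = self.descriptor_effect_sizes
        if np.isscalar(e):
            return np.full(self.n_descriptors, float(e))
        e = np.asarray(e, dtype=float)
        if len(e) != self.n_descriptors:
            raise ValueError("one effect size per descriptor required")
        return e


def theoretical_freq_p(p_pos: float, p_neg: float, positive_fraction: float) -> float:
    """Expected enrichment frequency of a planted bit: with expected counts,
    freq_P = p_pos / (pi * p_pos + (1 - pi) * p_neg)."""
    denom = positive_fraction * p_pos + (1 - positive_fraction) * p_neg
    return p_pos / denom if denom > 0 else 0.0


def generate_feature_dataset(
    spec: SyntheticSpec,
) -> tuple[LabeledDataset, FeatureBlock, FeatureBlock, dict]:
    """Draw a labelled synthetic dataset with fragment and descriptor blocks.

    Labels are Bernoulli(positive_fraction) draws, redrawn (bounded
    retries) if a single class comes out; label noise flips labels after
    feature generation, so features reflect the true class. Returns
    (dataset, binary block 'FRAG', continuous block 'DESC', ground truth).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_molecules

    true_labels = None
    for _ in range(100):
        draw = (rng.uniform(size=n) < spec.positive_fraction).astype(int)
        if 0 < draw.sum() < n:
            true_labels = draw
            break
    if true_labels is None:
        raise ValueError(
            "could not draw both classes; positive_fraction too extreme"
        )

    # fragment bits: planted alerts at class-conditional rates, the rest
    # at the background rate for both classes
    probs = np.full((n, spec.n_fragment_bits), spec.background_bit_probability)
    for idx, p_pos, p_neg in spec.planted_alerts:
        probs[:, idx] = np.where(true_labels == 1, p_pos, p_neg)
    frag = (rng.uniform(size=probs.shape) < probs).astype(float)

    # descriptors: unit-variance Gaussians, positives shifted by the effect size
    shifts = spec.effect_sizes
    desc = rng.normal(size=(n, spec.n_descriptors))
    desc[true_labels == 1] += shifts

    labels = true_labels.copy()
    if spec.label_noise > 0:
        flip = rng.uniform(size=n) < spec.label_noise
        labels[flip] = 1 - labels[flip]

    ids = [f"SYN{i:04d}" for i in range(n)]
    ds = LabeledDataset(
        [MoleculeRecord(i, "", int(l)) for i, l in zip(ids, labels)]
    )
    frag_block = FeatureBlock(
        "FRAG", "binary", frag, [f"frag_{j}" for j in range(spec.n_fragment_bits)],
        ids,
    )
    desc_block = FeatureBlock(
        "DESC", "continuous", desc,
        [f"desc_{j}" for j in range(spec.n_descriptors)], ids,
    )
    ground_truth = {
        "planted_alert_indices": [a[0] for a in spec.planted_alerts],
        "planted_alert_names": [f"frag_{a[0]}" for a in spec.planted_alerts],
        "theoretical_freq_P": {
            f"frag_{idx}": theoretical_freq_p(p_pos, p_neg, spec.positive_fraction)
            for idx, p_pos, p_neg in spec.planted_alerts
        },
        "true_labels": true_labels,
    }
    return ds, frag_block, desc_block, ground_truth


# Hand-validated simple structures: alkanes/alcohols, aromatics, amides,
# heteroaromatics and a beta-lactam-like ring. Labels are arbitrary but
# fixed, with both classes inside every prefix of length >= 4.
_FIXTURE: list[tuple[str, str, int]] = [
    ("FIX01", "C", 0),
    ("FIX02", "CC", 1),
    ("FIX03", "CCO", 0),
    ("FIX04", "c1ccccc1", 1),
    ("FIX05", "CC(=O)N", 1),
    ("FIX06", "CC(=O)O", 0),
    ("FIX07", "CCCC", 0),
    ("FIX08", "c1ccncc1", 1),
    ("FIX09", "O=C1CCN1", 1),
    ("FIX10", "CC(C)CO", 0),
    ("FIX11", "c1ccc2ccccc2c1", 0),
    ("FIX12", "CC(=O)Nc1ccccc1", 1),
    ("FIX13", "OCC(O)CO", 0),
    ("FIX14", "Clc1ccccc1", 1),
    ("FIX15", "CS(=O)(=O)N", 1),
    ("FIX16", "O", 0),
    ("FIX17", "CCN(CC)CC", 0),
    ("FIX18", "c1cc[nH]c1", 1),
    ("FIX19", "OC(=O)c1ccccc1O", 0),
    ("FIX20", "C1CCNCC1", 0),
    ("FIX21", "N#Cc1ccccc1", 1),
    ("FIX22", "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O", 1),
    ("FIX23", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", 0),
    ("FIX24", "CC(=O)Oc1ccccc1C(=O)O", 0),
]


def generate_smiles_fixture(n: int = 24) -> LabeledDataset:
    """First ``n`` molecules of the hardcoded SMILES fixture (4 <= n <= 24).

    Every SMILES is valid; repeated calls return the identical fixture.
    """
    if n < 4:
        raise ValueError("fixture needs n >= 4 to include both classes")
    if n > len(_FIXTURE):
        raise ValueError(f"fixture holds only {len(_FIXTURE)} molecules")
    return LabeledDataset(
        [MoleculeRecord(i, s, l) for i, s, l in _FIXTURE[:n]]
    )
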