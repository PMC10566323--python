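"""The 599-dimensional sequence descriptor engine.

Blocks, in order (599 = 9 + 20 + 400 + 21 + 21 + 105 + 23):

* basic (9): mean residue mass; charge (fraction positive {K,R,H}, fraction
  negative {D,E}, net charge per residue); polarity (fraction polar, fraction
  nonpolar); fraction aromatic {F,W,Y}; mean Kyte–Doolittle hydrophobicity;
  mean van der Waals volume.
* AAC (20): amino-acid composition, count(r)/l.
* DPC (400): overlapping dipeptide composition, count(rs)/(l-1).
* CTD (21/21/105): for each of 7 physicochemical attributes with residues
  partitioned into 3 classes — class fractions (Composition), unordered
  class-pair transition rates (Transition), and the positions (% of l) of
  the first, 25%, 50%, 75% and 100% occurrence of each class (Distribution).
* PseAAC (23): Chou-type pseudo amino-acid composition with lambda=3
  sequence-order correlation factors over three standardized residue
  properties (hydrophobicity, hydrophilicity, side-chain mass), weight 0.05.

Also provided: the per-residue 6-property min–max-normalized encoding used
by the hybrid recurrent models, and the ordinal (alphabetical rank) encoding
used by the embedding-based models.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _tables as T
from .io import AMINO_ACIDS, Dataset

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "N_FEATURES",
    "BLOCK_SLICES",
    "aac",
    "dpc",
    "ctd",
    "pseaac",
    "basic_descriptors",
    "full_feature_vector",
    "featurize_dataset",
    "residue_encoding",
    "ordinal_encode",
]

_AA_IDX = T.AA_INDEX
_DIPEPTIDES = ["".join(p) for p in itertools.product(AMINO_ACIDS, repeat=2)]

N_FEATURES = 599


def _check(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)} in sequence")
    return seq


# ---------------------------------------------------------------------------
# composition blocks
# ---------------------------------------------------------------------------

def aac(seq: str) -> np.ndarray:
    """Amino-acid composition: frequency of each residue (alphabetical)."""
    _check(seq)
    counts = np.zeros(20)
    for ch in seq:
        counts[_AA_IDX[ch]] += 1
    return counts / len(seq)


def dpc(seq: str) -> np.ndarray:
    """Dipeptide composition: overlapping 2-mer frequencies (400, AA..YY)."""
    _check(seq)
    if len(seq) < 2:
        raise ValueError("dipeptide composition requires length >= 2")
    counts = np.zeros(400)
    for a, b in zip(seq, seq[1:]):
        counts[_AA_IDX[a] * 20 + _AA_IDX[b]] += 1
    return counts / (len(seq) - 1)


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

_CTD_CLASS_OF = {
    attr: {aa: g for g, members in enumerate(groups) for aa in members}
    for attr, groups in T.CTD_CLASSES.items()
}


def ctd(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Composition / Transition / Distribution descriptors (21, 21, 105)."""
    _check(seq)
    L = len(seq)
    comp, trans, dist = [], [], []
    for attr in T.CTD_ATTRIBUTES:
        class_of = _CTD_CLASS_OF[attr]
        classes = [class_of[ch] for ch in seq]
        # composition: fraction of each of the 3 classes
        counts = [0, 0, 0]
        for c in classes:
            counts[c] += 1
        comp.extend(n / L for n in counts)
        # transition: (N(rs) + N(sr)) / (L - 1) for unordered pairs
        pair_counts = {(0, 1): 0, (0, 2): 0, (1, 2): 0}
        for c1, c2 in zip(classes, classes[1:]):
            if c1 != c2:
                pair_counts[(min(c1, c2), max(c1, c2))] += 1
        if L > 1:
            trans.extend(pair_counts[p] / (L - 1) for p in ((0, 1), (0, 2), (1, 2)))
        else:
            trans.extend([0.0, 0.0, 0.0])
        # distribution: % position of 1st, 25%, 50%, 75%, 100% occurrence
        for g in range(3):
            positions = [i + 1 for i, c in enumerate(classes) if c == g]
            if not positions:
                dist.extend([0.0] * 5)
                continue
            n = len(positions)
            for frac in (0.0, 0.25, 0.50, 0.75, 1.0):
                k = max(1, math.ceil(frac * n))
                dist.append(positions[k - 1] / L * 100.0)
    return np.array(comp), np.array(trans), np.array(dist)


# ---------------------------------------------------------------------------
# PseAAC
# ---------------------------------------------------------------------------

def _standardized_properties() -> np.ndarray:
    """3 x 20 matrix of zero-mean unit-variance residue properties."""
    mats = []
    for table in (
        T.PSEAAC_HYDROPHOBICITY,
        T.PSEAAC_HYDROPHILICITY,
        T.PSEAAC_SIDECHAIN_MASS,
    ):
        vals = np.array([table[aa] for aa in AMINO_ACIDS])
        mats.append((vals - vals.mean()) / vals.std())
    return np.vstack(mats)


_PSEAAC_PROPS = _standardized_properties()


def _theta(a: str, b: str) -> float:
    """Mean squared property difference between two residues."""
    pa = _PSEAAC_PROPS[:, _AA_IDX[a]]
    pb = _PSEAAC_PROPS[:, _AA_IDX[b]]
    return float(np.mean((pb - pa) ** 2))


def pseaac(seq: str, lam: int = 3, weight: float = 0.05) -> np.ndarray:
    """Chou-type pseudo amino-acid composition (20 + lam components)."""
    _check(seq)
    L = len(seq)
    if L <= lam:
        raise ValueError(f"pseaac needs length > lambda ({lam}), got {L}")
    freqs = aac(seq)
    thetas = np.array(
        [
            sum(_theta(seq[i], seq[i + j]) for i in range(L - j)) / (L - j)
            for j in range(1, lam + 1)
        ]
    )
    denom = freqs.sum() + weight * thetas.sum()
    return np.concatenate([freqs / denom, weight * thetas / denom])


# ---------------------------------------------------------------------------
# basic descriptors
# ---------------------------------------------------------------------------

def basic_descriptors(seq: str) -> np.ndarray:
    """The 9 basic global descriptors (see module docstring for order)."""
    _check(seq)
    L = len(seq)
    n_pos = sum(seq.count(aa) for aa in T.POSITIVE_RESIDUES)
    n_neg = sum(seq.count(aa) for aa in T.NEGATIVE_RESIDUES)
    return np.array(
        [
            sum(T.RESIDUE_MASS[ch] for ch in seq) / L,
            n_pos / L,
            n_neg / L,
            (n_pos - n_neg) / L,
            sum(seq.count(aa) for aa in T.POLAR_RESIDUES) / L,
            sum(seq.count(aa) for aa in T.NONPOLAR_RESIDUES) / L,
            sum(seq.count(aa) for aa in T.AROMATIC_RESIDUES) / L,
            sum(T.KYTE_DOOLITTLE[ch] for ch in seq) / L,
            sum(T.VDW_VOLUME[ch] for ch in seq) / L,
        ]
    )


# ---------------------------------------------------------------------------
# assembled feature vector
# ---------------------------------------------------------------------------

def _feature_names() -> list[str]:
    names = [
        "basic_mean_residue_mass",
        "basic_frac_positive",
        "basic_frac_negative",
        "basic_net_charge_per_residue",
        "basic_frac_polar",
        "basic_frac_nonpolar",
        "basic_frac_aromatic",
        "basic_mean_hydrophobicity",
        "basic_mean_vdw_volume",
    ]
    names += [f"AAC_{aa}" for aa in AMINO_ACIDS]
    names += [f"DPC_{dp}" for dp in _DIPEPTIDES]
    pairs = ("G1G2", "G1G3", "G2G3")
    names += [f"CTDC_{attr}_G{g + 1}" for attr in T.CTD_ATTRIBUTES for g in range(3)]
    names += [f"CTDT_{attr}_{p}" for attr in T.CTD_ATTRIBUTES for p in pairs]
    names += [
        f"CTDD_{attr}_G{g + 1}_P{p}"
        for attr in T.CTD_ATTRIBUTES
        for g in range(3)
        for p in (0, 25, 50, 75, 100)
    ]
    names += [f"PAAC_{aa}" for aa in AMINO_ACIDS]
    names += [f"PAAC_theta{j}" for j in (1, 2, 3)]
    return names


FEATURE_NAMES: list[str] = _feature_names()
assert len(FEATURE_NAMES) == N_FEATURES

_BLOCK_SIZES = {"basic": 9, "aac": 20, "dpc": 400, "ctd_c": 21, "ctd_t": 21, "ctd_d": 105, "pseaac": 23}


def _block_slices() -> dict[str, slice]:
    slices, start = {}, 0
    for name, size in _BLOCK_SIZES.items():
        slices[name] = slice(start, start + size)
        start += size
    return slices


BLOCK_SLICES: dict[str, slice] = _block_slices()


@dataclass(frozen=True)
class FeatureVector:
    """599 named descriptor values for one protein."""

    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {self.values.shape}")

    def block(self, name: str) -> np.ndarray:
        return self.values[BLOCK_SLICES[name]]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=FEATURE_NAMES)


def full_feature_vector(seq: str) -> FeatureVector:
    """Concatenate basic‖AAC‖DPC‖CTD-C‖CTD-T‖CTD-D‖PseAAC (599 values)."""
    _check(seq)
    if len(seq) <= 3:
        raise ValueError("full feature vector requires length > 3")
    c, t, d = ctd(seq)
    return FeatureVector(
        np.concatenate([basic_descriptors(seq), aac(seq), dpc(seq), c, t, d, pseaac(seq)])
    )


def featurize_dataset(ds: Dataset) -> pd.DataFrame:
    """599-column feature table indexed by record id."""
    rows = [full_feature_vector(rec.sequence).values for rec in ds]
    return pd.DataFrame(rows, index=ds.ids, columns=FEATURE_NAMES)


# ---------------------------------------------------------------------------
# per-residue encodings
# ---------------------------------------------------------------------------

def _encoding_table() -> np.ndarray:
    """20 x 6 min–max-normalized property table (rows alphabetical)."""
    cols = []
    for _, table in T.RESIDUE_ENCODING_PROPERTIES:
        vals = np.array([table[aa] for aa in AMINO_ACIDS])
        cols.append((vals - vals.min()) / (vals.max() - vals.min()))
    return np.column_stack(cols)


RESIDUE_ENCODING_TABLE = _encoding_table()


def residue_encoding(seq: str) -> np.ndarray:
    """l x 6 matrix of min–max normalized physicochemical properties
    (weight, charge, polarity, aromaticity, hydrophobicity, vdW volume)."""
    _check(seq)
    idx = [_AA_IDX[ch] for ch in seq]
    return RESIDUE_ENCODING_TABLE[idx]


def ordinal_encode(seq: str) -> np.ndarray:
    """Alphabetical ordinal codes in {1..20} (A→1, C→2, …, Y→20)."""
    _check(seq)
    return np.array([_AA_IDX[ch] + 1 for ch in seq], dtype=np.int64)
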