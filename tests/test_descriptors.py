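"""Descriptor engine versus independently coded brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from thermoseq import _tables as T
from thermoseq.descriptors import (
    BLOCK_SLICES,
    FEATURE_NAMES,
    N_FEATURES,
    aac,
    basic_descriptors,
    ctd,
    dpc,
    full_feature_vector,
    ordinal_encode,
    pseaac,
    residue_encoding,
)
from thermoseq.io import AMINO_ACIDS


def random_seq(rng, n):
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


# ---------------------------------------------------------------------------
# oracles (deliberately naive, independent of the implementation)
# ---------------------------------------------------------------------------

def oracle_aac(seq):
    return np.array([seq.count(aa) / len(seq) for aa in AMINO_ACIDS])


def oracle_dpc(seq):
    out = []
    for a, b in itertools.product(AMINO_ACIDS, repeat=2):
        count = sum(1 for i in range(len(seq) - 1) if seq[i] == a and seq[i + 1] == b)
        out.append(count / (len(seq) - 1))
    return np.array(out)


def oracle_ctd(seq):
    comp, trans, dist = [], [], []
    L = len(seq)
    for attr in T.CTD_ATTRIBUTES:
        groups = T.CTD_CLASSES[attr]
        cls = []
        for ch in seq:
            for g, members in enumerate(groups):
                if ch in members:
                    cls.append(g)
                    break
        for g in range(3):
            comp.append(cls.count(g) / L)
        for g1, g2 in ((0, 1), (0, 2), (1, 2)):
            n = sum(
                1
                for i in range(L - 1)
                if {cls[i], cls[i + 1]} == {g1, g2}
            )
            trans.append(n / (L - 1) if L > 1 else 0.0)
        for g in range(3):
            pos = [i + 1 for i in range(L) if cls[i] == g]
            if not pos:
                dist.extend([0.0] * 5)
                continue
            for frac in (0, 0.25, 0.5, 0.75, 1.0):
                k = max(1, math.ceil(frac * len(pos)))
                dist.append(pos[k - 1] / L * 100.0)
    return np.array(comp), np.array(trans), np.array(dist)


def oracle_pseaac(seq, lam=3, w=0.05):
    props = []
    for table in (T.PSEAAC_HYDROPHOBICITY, T.PSEAAC_HYDROPHILICITY, T.PSEAAC_SIDECHAIN_MASS):
        vals = np.array([table[aa] for aa in AMINO_ACIDS])
        props.append(dict(zip(AMINO_ACIDS, (vals - vals.mean()) / vals.std())))

    def theta(a, b):
        return sum((p[b] - p[a]) ** 2 for p in props) / 3.0

    L = len(seq)
    thetas = []
    for j in range(1, lam + 1):
        total = sum(theta(seq[i], seq[i + j]) for i in range(L - j))
        thetas.append(total / (L - j))
    f = [seq.count(aa) / L for aa in AMINO_ACIDS]
    denom = sum(f) + w * sum(thetas)
    return np.array([x / denom for x in f] + [w * t / denom for t in thetas])


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

def test_aac_examples():
    v = aac("AAAA")
    assert v[0] == 1.0 and v.sum() == 1.0
    v = aac("ACCA")
    assert v[AMINO_ACIDS.index("A")] == 0.5
    assert v[AMINO_ACIDS.index("C")] == 0.5


def test_dpc_examples():
    v = dpc("ACAC")
    ac = AMINO_ACIDS.index("A") * 20 + AMINO_ACIDS.index("C")
    ca = AMINO_ACIDS.index("C") * 20 + AMINO_ACIDS.index("A")
    assert v[ac] == pytest.approx(2 / 3)
    assert v[ca] == pytest.approx(1 / 3)
    assert dpc("AA")[0] == 1.0
    with pytest.raises(ValueError):
        dpc("A")


def test_ctd_homopolymer_and_pair():
    comp, trans, _ = ctd("KKKKK")  # K: charge class 1 throughout
    charge_offset = list(T.CTD_ATTRIBUTES).index("charge") * 3
    assert comp[charge_offset] == 1.0  # group1 of charge is "KR"
    assert trans[charge_offset : charge_offset + 3].sum() == 0.0
    _, trans2, _ = ctd("KD")  # K in charge group1, D in group3
    assert trans2[charge_offset + 1] == 1.0  # pair (G1, G3)


def test_pseaac_homopolymer_and_normalization():
    v = pseaac("AAAAA")
    assert v[AMINO_ACIDS.index("A")] == pytest.approx(1.0)
    assert v[20:].sum() == pytest.approx(0.0)
    rng = np.random.RandomState(1)
    v2 = pseaac(random_seq(rng, 40))
    assert v2.sum() == pytest.approx(1.0)
    assert (v2 >= 0).all()
    with pytest.raises(ValueError):
        pseaac("ACD", lam=3)


def test_basic_descriptor_examples():
    v = basic_descriptors("KKKK")
    assert v[1] == 1.0 and v[2] == 0.0 and v[3] == 1.0
    assert basic_descriptors("AAAA")[7] == pytest.approx(1.8)  # Kyte-Doolittle A
    assert basic_descriptors("FFWWYY")[6] == 1.0


# ---------------------------------------------------------------------------
# oracle agreement on random fixtures
# ---------------------------------------------------------------------------

def test_blocks_match_bruteforce_oracles():
    rng = np.random.RandomState(42)
    for _ in range(100):
        seq = random_seq(rng, rng.randint(10, 200))
        np.testing.assert_allclose(aac(seq), oracle_aac(seq), atol=1e-12)
        np.testing.assert_allclose(dpc(seq), oracle_dpc(seq), atol=1e-12)
        for mine, ref in zip(ctd(seq), oracle_ctd(seq)):
            np.testing.assert_allclose(mine, ref, atol=1e-12)
        np.testing.assert_allclose(pseaac(seq), oracle_pseaac(seq), atol=1e-12)


def test_full_vector_shape_and_blocks():
    rng = np.random.RandomState(7)
    seq = random_seq(rng, 100)
    fv = full_feature_vector(seq)
    assert fv.values.shape == (N_FEATURES,)
    assert len(FEATURE_NAMES) == 599
    np.testing.assert_array_equal(fv.values[9:29], aac(seq))  # AAC block position
    np.testing.assert_array_equal(fv.block("pseaac"), pseaac(seq))
    fv2 = full_feature_vector(seq)
    np.testing.assert_array_equal(fv.values, fv2.values)  # deterministic


def test_block_sizes():
    sizes = {k: s.stop - s.start for k, s in BLOCK_SLICES.items()}
    assert sizes == {
        "basic": 9, "aac": 20, "dpc": 400, "ctd_c": 21, "ctd_t": 21,
        "ctd_d": 105, "pseaac": 23,
    }


def test_composition_invariants():
    rng = np.random.RandomState(3)
    seq = random_seq(rng, 150)
    # AAC exactly invariant under sequence duplication
    np.testing.assert_allclose(aac(seq + seq), aac(seq), atol=1e-12)
    # CTD composition sums to 1 per attribute
    comp, _, _ = ctd(seq)
    np.testing.assert_allclose(comp.reshape(7, 3).sum(axis=1), 1.0, atol=1e-12)
    assert dpc(seq).sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# per-residue encodings
# ---------------------------------------------------------------------------

def test_residue_encoding_properties():
    enc = residue_encoding("ACD")
    assert enc.shape == (3, 6)
    assert (enc >= 0).all() and (enc <= 1).all()
    # rows for equal residues are equal
    enc2 = residue_encoding("AA")
    np.testing.assert_array_equal(enc2[0], enc2[1])
    # the heaviest residue (W) has normalized weight 1.0
    assert residue_encoding("W")[0, 0] == 1.0
    # lookup-table oracle
    for i, aa in enumerate("ACD"):
        for j, (_, table) in enumerate(T.RESIDUE_ENCODING_PROPERTIES):
            vals = np.array([table[x] for x in AMINO_ACIDS])
            expect = (table[aa] - vals.min()) / (vals.max() - vals.min())
            assert enc[i, j] == pytest.approx(expect)


def test_ordinal_encoding():
    np.testing.assert_array_equal(ordinal_encode("A"), [1])
    np.testing.assert_array_equal(ordinal_encode("Y"), [20])
    np.testing.assert_array_equal(ordinal_encode("ACY"), [1, 2, 20])
    with pytest.raises(ValueError):
        ordinal_encode("ABC")  # B is not an amino acid
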