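"""Labeled, species-structured synthetic protein datasets.

The generator emulates the structure of a two-class thermophilicity
benchmark: each species draws an optimal growth temperature from its class
range (thermophilic >= 60 degrees C, nonthermophilic <= 30), a
species-specific residue distribution, and several proteins whose lengths
are uniform over the benchmark's observed range [82, 712]. Thermophilic
species' residue distributions are shifted toward a designated residue
subset (default: the charged residues D, E, K, R — a fixture choice, not a
biological claim) by a logit shift proportional to ``effect_size``, so the
label signal lives at the composition level, which every model family in
the zoo can detect; ``effect_size = 0`` yields label-free data. Everything
is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import AMINO_ACIDS, Dataset, ProteinRecord, write_fasta_with_metadata

__all__ = ["GeneratorConfig", "generate", "make_golden_fixtures"]

#: logit shift applied to the enriched subset per unit of effect size
_SHIFT_PER_EFFECT = 0.5
#: species-to-species compositional noise (logit scale)
_SPECIES_SIGMA = 0.3


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults follow the benchmark's labeling rule (thermophilic species have
    OGT in [60, 95] degrees C, nonthermophilic in [20, 30]) and length range
    [82, 712]; species and per-species protein counts default to a desk-scale
    dataset of a few hundred proteins with many species per class.
    """

    n_species_thermo: int = 20
    n_species_meso: int = 30
    proteins_per_species: tuple[int, int] = (5, 15)
    length_range: tuple[int, int] = (82, 712)
    ogt_thermo_range: tuple[float, float] = (60.0, 95.0)
    ogt_meso_range: tuple[float, float] = (20.0, 30.0)
    effect_size: float = 1.0
    enriched_residues: str = "DEKR"
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.length_range, self.ogt_thermo_range, self.ogt_meso_range):
            if lo > hi:
                raise ValueError(f"range ({lo}, {hi}) not well-ordered")
        if self.ogt_thermo_range[0] < 60.0:
            raise ValueError("thermophilic OGT range must start at or above 60 degrees C")
        if self.ogt_meso_range[1] > 30.0:
            raise ValueError("nonthermophilic OGT range must end at or below 30 degrees C")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")


def _species_distribution(rng: np.random.RandomState, cfg: GeneratorConfig, thermo: bool) -> np.ndarray:
    logits = rng.normal(0.0, _SPECIES_SIGMA, 20)
    if thermo and cfg.effect_size > 0:
        for aa in cfg.enriched_residues:
            logits[AMINO_ACIDS.index(aa)] += cfg.effect_size * _SHIFT_PER_EFFECT
    weights = np.exp(logits)
    return weights / weights.sum()


def generate(cfg: GeneratorConfig) -> Dataset:
    """Draw a species-structured labeled dataset from the configuration."""
    rng = np.random.RandomState(cfg.seed)
    aa = np.array(list(AMINO_ACIDS))
    records: list[ProteinRecord] = []
    specs = [(f"Thermus_synthetic_{i:03d}", True) for i in range(cfg.n_species_thermo)]
    specs += [(f"Mesophilus_synthetic_{i:03d}", False) for i in range(cfg.n_species_meso)]
    for species, thermo in specs:
        ogt_lo, ogt_hi = cfg.ogt_thermo_range if thermo else cfg.ogt_meso_range
        ogt = float(rng.uniform(ogt_lo, ogt_hi))
        dist = _species_distribution(rng, cfg, thermo)
        n_proteins = int(rng.randint(cfg.proteins_per_species[0], cfg.proteins_per_species[1] + 1))
        for p in range(n_proteins):
            length = int(rng.randint(cfg.length_range[0], cfg.length_range[1] + 1))
            seq = "".join(rng.choice(aa, size=length, p=dist))
            records.append(
                ProteinRecord(
                    id=f"{species}|P{p:04d}",
                    sequence=seq,
                    species=species,
                    ogt=ogt,
                    label=int(ogt >= 60.0),
                )
            )
    return Dataset(records, provenance=f"synthetic(seed={cfg.seed},effect={cfg.effect_size})")


# ---------------------------------------------------------------------------
# small frozen fixtures for module tests
# ---------------------------------------------------------------------------

def _mutate(seq: str, n_sub: int, rng: np.random.RandomState) -> str:
    """Substitute ``n_sub`` random positions (keeps length, high identity)."""
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_sub, replace=False):
        chars[pos] = AMINO_ACIDS[rng.randint(20)]
    return "".join(chars)


def make_golden_fixtures(out_dir: str | Path, seed: int = 17) -> dict[str, tuple[Path, Path]]:
    """Write the small FASTA+TSV fixture sets used across the test suite.

    * ``separable`` — strong composition signal (effect size 2).
    * ``zero_signal`` — effect size 0, labels carry no sequence information.
    * ``redundancy`` — a planted cluster of 5 near-identical copies plus
      unrelated singletons; greedy clustering must collapse the cluster.
    * ``holdout`` — species-structured set where two test-species proteins
      are planted >50%-identity homologs of training proteins.

    Returns {name: (fasta_path, meta_path)}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, tuple[Path, Path]] = {}

    def _write(name: str, ds: Dataset):
        fasta = out_dir / f"{name}.fasta"
        meta = out_dir / f"{name}.tsv"
        write_fasta_with_metadata(ds, fasta, meta)
        written[name] = (fasta, meta)

    small = dict(
        n_species_thermo=4, n_species_meso=6, proteins_per_species=(4, 6),
        length_range=(82, 160),
    )
    _write("separable", generate(GeneratorConfig(effect_size=2.0, seed=seed, **small)))
    _write("zero_signal", generate(GeneratorConfig(effect_size=0.0, seed=seed + 1, **small)))

    rng = np.random.RandomState(seed + 2)
    base = generate(
        GeneratorConfig(
            n_species_thermo=2, n_species_meso=2, proteins_per_species=(3, 3),
            length_range=(90, 120), effect_size=0.0, seed=seed + 2,
        )
    )
    seed_seq = base.records[0].sequence
    planted = [
        ProteinRecord(id=f"cluster|C{i}", sequence=_mutate(seed_seq, 2, rng),
                      species="Clusterus_plantus", ogt=65.0, label=1)
        for i in range(5)
    ]
    _write("redundancy", Dataset(planted + base.records[1:], provenance="redundancy fixture"))

    holdout_base = generate(
        GeneratorConfig(
            n_species_thermo=4, n_species_meso=6, proteins_per_species=(3, 4),
            length_range=(90, 140), effect_size=1.0, seed=seed + 3,
        )
    )
    train_recs = [r for r in holdout_base.records if not r.species.endswith("003")
                  and not r.species.endswith("005")]
    test_recs = [r for r in holdout_base.records if r.species.endswith("003")
                 or r.species.endswith("005")]
    # plant two cross-set homologs: near-copies of training sequences living
    # in held-out species (they must fail a <50%-identity relatedness filter)
    homolog_rng = np.random.RandomState(seed + 4)
    for j, src in enumerate(train_recs[:2]):
        test_recs.append(
            ProteinRecord(
                id=f"homolog|H{j}", sequence=_mutate(src.sequence, 3, homolog_rng),
                species=test_recs[0].species, ogt=test_recs[0].ogt, label=test_recs[0].label,
            )
        )
    _write("holdout_train", Dataset(train_recs, provenance="holdout fixture (train)"))
    _write("holdout_test", Dataset(test_recs, provenance="holdout fixture (test)"))
    return written
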