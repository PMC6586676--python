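"""Forward simulation of low-coverage allele read counts with known truth.

The simulator emulates the statistical structure of a two-species
shotgun-sequencing study: a pair of species panels whose allele frequencies
at biallelic sites are mostly fixed for alternate alleles (with smaller
fractions of species-private and shared polymorphism), diploid panel
individuals sequenced to very low mean depth, and a single focal specimen
whose genotype is defined by a pedigree (pure, F1, F2, backcrosses).

Reads are drawn per individual per site with Poisson depth, each read
sampled uniformly from the two genotype alleles and flipped with a small
symmetric error probability. There is no linkage: sites are independent,
matching the independence assumption of the downstream binomial ancestry
likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesPairModel",
    "SequencingModel",
    "Pedigree",
    "PEDIGREES",
    "DEFAULT_SCENARIOS",
    "get_pedigree",
    "simulate_frequencies",
    "simulate_panel",
    "simulate_hybrid",
    "simulate_single_read_matches",
    "simulate_coverage_profile",
    "simulate_dataset",
]

SITE_CLASSES = ("fixed_difference", "poly_A_only", "poly_B_only", "poly_both", "monomorphic")


class ConfigurationError(ValueError):
    """Raised when a simulation model is internally inconsistent."""


@dataclass(frozen=True)
class SpeciesPairModel:
    """Per-site allele-frequency model for a pair of diverged species.

    Class proportions default to the breakdown observed in a
    beluga/narwhal fixed-difference panel (78.0% fixed, 13.2% / 6.2%
    species-private polymorphic, 2.6% polymorphic in both); the remainder
    (if any) is monomorphic-identical. Within-species minor allele
    frequencies are uniform on [maf_low, maf_high].
    """

    n_sites: int
    prop_fixed: float = 0.780
    prop_poly_a: float = 0.132
    prop_poly_b: float = 0.062
    prop_poly_both: float = 0.026
    maf_low: float = 0.05
    maf_high: float = 0.5

    def validate(self) -> None:
        props = (self.prop_fixed, self.prop_poly_a, self.prop_poly_b, self.prop_poly_both)
        if self.n_sites <= 0:
            raise ConfigurationError("n_sites must be positive")
        if any(p < 0 for p in props) or sum(props) > 1 + 1e-12:
            raise ConfigurationError(
                "class proportions must be nonnegative and sum to at most 1"
            )
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ConfigurationError("need 0 < maf_low <= maf_high <= 0.5")


@dataclass(frozen=True)
class SequencingModel:
    """Poisson read depth plus symmetric per-read allele-flip error."""

    mean_depth: float = 0.2
    error_rate: float = 0.002

    def validate(self) -> None:
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be positive")
        if not (0 <= self.error_rate < 0.5):
            raise ConfigurationError("error_rate must be in [0, 0.5)")


@dataclass(frozen=True)
class Pedigree:
    """A named hybridization scenario.

    ``parents`` is None for pure-species founders, otherwise a pair of
    pedigree names recursed when drawing gametes. ``expected_b`` is the
    expected fraction of the genome inherited from species A.
    """

    name: str
    expected_b: float
    parents: Optional[tuple[str, str]] = None


PEDIGREES: dict[str, Pedigree] = {
    p.name: p
    for p in (
        Pedigree("pure_A", 1.0),
        Pedigree("pure_B", 0.0),
        Pedigree("F1", 0.5, ("pure_A", "pure_B")),
        Pedigree("F2", 0.5, ("F1", "F1")),
        Pedigree("BC1A", 0.75, ("F1", "pure_A")),
        Pedigree("BC1B", 0.25, ("F1", "pure_B")),
        Pedigree("BC2A", 0.875, ("BC1A", "pure_A")),
        Pedigree("BC2B", 0.125, ("BC1B", "pure_B")),
    )
}

#: The seven-scenario comparison set: expected species-A ancestry
#: {1, .875, .75, .5, .25, .125, 0}.
DEFAULT_SCENARIOS: tuple[str, ...] = (
    "pure_A",
    "BC2A",
    "BC1A",
    "F1",
    "BC1B",
    "BC2B",
    "pure_B",
)


def get_pedigree(name: str) -> Pedigree:
    try:
        return PEDIGREES[name]
    except KeyError:
        raise KeyError(
            f"unknown pedigree {name!r}; known: {sorted(PEDIGREES)}"
        ) from None


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_frequencies(
    model: SpeciesPairModel, seed=None
) -> pd.DataFrame:
    """Draw paired per-site allele-1 frequencies for species A and B.

    Returns a DataFrame with columns ``f_a``, ``f_b`` and the truth label
    ``true_class``. At fixed-difference sites the pair is exactly (1, 0)
    or (0, 1); at species-private polymorphic sites one species segregates
    while the other is fixed; monomorphic sites are fixed for the same
    allele in both species.
    """
    model.validate()
    rng = _as_rng(seed)
    n = model.n_sites

    probs = np.array(
        [
            model.prop_fixed,
            model.prop_poly_a,
            model.prop_poly_b,
            model.prop_poly_both,
        ]
    )
    probs = np.append(probs, max(0.0, 1.0 - probs.sum()))
    labels = rng.choice(5, size=n, p=probs / probs.sum())

    f_a = np.empty(n)
    f_b = np.empty(n)

    def maf(k: int) -> np.ndarray:
        m = rng.uniform(model.maf_low, model.maf_high, size=k)
        flip = rng.random(k) < 0.5  # random major/minor orientation
        return np.where(flip, m, 1.0 - m)

    fixed = labels == 0
    orient = rng.random(fixed.sum()) < 0.5
    f_a[fixed] = np.where(orient, 1.0, 0.0)
    f_b[fixed] = np.where(orient, 0.0, 1.0)

    pa = labels == 1
    f_a[pa] = maf(pa.sum())
    f_b[pa] = (rng.random(pa.sum()) < 0.5).astype(float)

    pb = labels == 2
    f_b[pb] = maf(pb.sum())
    f_a[pb] = (rng.random(pb.sum()) < 0.5).astype(float)

    both = labels == 3
    f_a[both] = maf(both.sum())
    f_b[both] = maf(both.sum())

    mono = labels == 4
    shared = (rng.random(mono.sum()) < 0.5).astype(float)
    f_a[mono] = shared
    f_b[mono] = shared

    return pd.DataFrame(
        {
            "f_a": f_a,
            "f_b": f_b,
            "true_class": np.array(SITE_CLASSES)[labels],
        }
    )


def _read_counts_from_genotype(
    geno: np.ndarray, seq: SequencingModel, rng: np.random.Generator
) -> np.ndarray:
    """Sample (…, 2) read counts of allele 1 / allele 2 given allele-1 dosage."""
    depth = rng.poisson(seq.mean_depth, size=geno.shape)
    # P(read = allele 1) given dosage g: sample one of the two genotype
    # alleles uniformly, then flip with error_rate.
    p1 = (geno / 2.0) * (1 - seq.error_rate) + (1 - geno / 2.0) * seq.error_rate
    a1 = rng.binomial(depth, p1)
    return np.stack([a1, depth - a1], axis=-1)


def simulate_panel(
    freqs: np.ndarray, n_individuals: int, seq: SequencingModel, seed=None
) -> np.ndarray:
    """Simulate a species panel: (n_individuals, n_sites, 2) read counts.

    Genotypes are Hardy–Weinberg draws (two independent alleles) from the
    per-site allele-1 frequencies ``freqs``; individuals are unrelated.
    """
    seq.validate()
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or np.any((freqs < 0) | (freqs > 1)):
        raise ConfigurationError("freqs must be a 1-D array of probabilities")
    if n_individuals < 1:
        raise ConfigurationError("n_individuals must be >= 1")
    rng = _as_rng(seed)
    geno = rng.binomial(2, freqs[None, :], size=(n_individuals, freqs.size))
    return _read_counts_from_genotype(geno, seq, rng)


def _gamete(
    ped: Pedigree, f_a: np.ndarray, f_b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One transmitted allele per site (1 = allele 1), recursing the recipe."""
    if ped.parents is None:
        f = f_a if ped.name == "pure_A" else f_b
        return (rng.random(f_a.size) < f).astype(np.int8)
    g1 = _gamete(get_pedigree(ped.parents[0]), f_a, f_b, rng)
    g2 = _gamete(get_pedigree(ped.parents[1]), f_a, f_b, rng)
    pick = rng.random(f_a.size) < 0.5
    return np.where(pick, g1, g2)


def hybrid_genotype(
    pedigree: str | Pedigree, f_a: np.ndarray, f_b: np.ndarray, seed=None
) -> np.ndarray:
    """Per-site allele-1 dosage (0/1/2) of a pedigree-defined individual."""
    ped = get_pedigree(pedigree) if isinstance(pedigree, str) else pedigree
    if ped.parents is None:
        f = np.asarray(f_a if ped.name == "pure_A" else f_b, dtype=float)
        rng = _as_rng(seed)
        return rng.binomial(2, f)
    rng = _as_rng(seed)
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    p1, p2 = (get_pedigree(n) for n in ped.parents)
    return (_gamete(p1, f_a, f_b, rng) + _gamete(p2, f_a, f_b, rng)).astype(np.int8)


def simulate_hybrid(
    pedigree: str | Pedigree,
    f_a: np.ndarray,
    f_b: np.ndarray,
    seq: SequencingModel,
    seed=None,
) -> np.ndarray:
    """Simulate the focal specimen: (n_sites, 2) read counts of allele 1/2.

    The genotype at each site is formed from two gametes drawn by recursing
    the pedigree recipe (each gamete picks one of the parent's two alleles
    uniformly); reads are then sampled exactly as for panel individuals.
    """
    seq.validate()
    rng = _as_rng(seed)
    geno = hybrid_genotype(pedigree, f_a, f_b, rng)
    return _read_counts_from_genotype(geno, seq, rng)


def simulate_single_read_matches(
    pedigree: str | Pedigree, n_sites: int, error_rate: float = 0.0, seed=None
) -> tuple[int, int]:
    """Counts of single focal reads matching the A / B allele at fixed sites.

    Convenience path for power and calibration studies: every site is a
    fixed difference (f_a=1, f_b=0) covered by exactly one focal read, so
    the result is the pair (n_b, n_n) fed to the ancestry tests.
    """
    rng = _as_rng(seed)
    ones = np.ones(n_sites)
    geno = hybrid_genotype(pedigree, ones, 1.0 - ones, rng)
    p1 = (geno / 2.0) * (1 - error_rate) + (1 - geno / 2.0) * error_rate
    match_a = rng.random(n_sites) < p1
    n_b = int(match_a.sum())
    return n_b, n_sites - n_b


def simulate_coverage_profile(
    sex: str,
    autosomal_rate: float,
    n_x_sites: int = 20_000,
    n_auto_sites: int = 50_000,
    seed=None,
):
    """Poisson per-site depths on X-linked and autosomal partitions.

    Males carry one X, so the X-linked Poisson rate is half the autosomal
    rate; females have equal rates.
    """
    from .coverage import CoverageProfile

    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if autosomal_rate <= 0:
        raise ConfigurationError("autosomal_rate must be positive")
    rng = _as_rng(seed)
    x_rate = autosomal_rate / 2.0 if sex == "male" else autosomal_rate
    return CoverageProfile(
        x_depths=rng.poisson(x_rate, n_x_sites).astype(float),
        auto_depths=rng.poisson(autosomal_rate, n_auto_sites).astype(float),
        provenance=f"simulated:{sex}",
    )


_BASES = np.array(list("ACGT"))


def simulate_dataset(
    model: SpeciesPairModel,
    pedigree: str | Pedigree = "F1",
    n_panel_a: int = 8,
    n_panel_b: int = 8,
    panel_seq: SequencingModel = SequencingModel(mean_depth=0.24),
    panel_seq_b: Optional[SequencingModel] = None,
    focal_seq: SequencingModel = SequencingModel(mean_depth=0.05),
    seed=None,
):
    """Full synthetic study: panels + focal specimen as a SiteTable.

    Defaults mirror the study design: eight individuals per species panel
    at ~0.24x / ~0.18x mean depth and a focal specimen at ~0.05x.

    Returns ``(SiteTable, truth)`` where ``truth`` is the frequency table
    from :func:`simulate_frequencies` with a ``site_id`` column prepended.
    """
    from .sites import SiteTable

    rng = _as_rng(seed)
    freqs = simulate_frequencies(model, rng)
    f_a = freqs["f_a"].to_numpy()
    f_b = freqs["f_b"].to_numpy()
    seq_b = panel_seq_b if panel_seq_b is not None else SequencingModel(
        mean_depth=0.18, error_rate=panel_seq.error_rate
    )

    counts_a = simulate_panel(f_a, n_panel_a, panel_seq, rng)
    counts_b = simulate_panel(f_b, n_panel_b, seq_b, rng)
    counts_f = simulate_hybrid(pedigree, f_a, f_b, focal_seq, rng)

    n = model.n_sites
    site_id = np.array([f"s{i:07d}" for i in range(n)])
    base1 = rng.integers(0, 4, size=n)
    base2 = (base1 + rng.integers(1, 4, size=n)) % 4  # distinct second allele

    data = {"site_id": site_id, "allele1": _BASES[base1], "allele2": _BASES[base2]}
    species: dict[str, str] = {}
    for i in range(n_panel_a):
        iid = f"A{i + 1:02d}"
        species[iid] = "A"
        data[f"{iid}__a1"] = counts_a[i, :, 0]
        data[f"{iid}__a2"] = counts_a[i, :, 1]
    for i in range(n_panel_b):
        iid = f"B{i + 1:02d}"
        species[iid] = "B"
        data[f"{iid}__a1"] = counts_b[i, :, 0]
        data[f"{iid}__a2"] = counts_b[i, :, 1]
    species["FOCAL"] = "focal"
    data["FOCAL__a1"] = counts_f[:, 0]
    data["FOCAL__a2"] = counts_f[:, 1]

    table = SiteTable(pd.DataFrame(data), species)
    truth = freqs.copy()
    truth.insert(0, "site_id", site_id)
    return table, truth
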