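"""Synthetic inputs for the whole pipeline.

Three generators, all deterministic under a seed:

* class-conditional feature vectors per (motif, UNM/MOD) with a tunable
  separation knob, emulating the hidden-layer features a neural basecaller
  would provide for a candidate adenosine;
* concatemer reads built from ligated-oligo designs (random-ligation
  homopolymers, splint-ligation heteropolymers, and the two benchmark
  designs: a two-motif contrast and a 13-nt periodic repeat whose m6A
  pattern cycles every 26 nt with a read-to-read phase shift of 0 or 13 nt);
* transcriptome-scale site simulations with true per-site stoichiometries,
  coverage distributions, WT/IVT mixing fractions and a knockout arm.

The feature stand-in is a pair of spherical Gaussians per (motif, class).
Both class centers share a fixed large "pedestal" coordinate (8x the noise
scale) so that per-vector max-abs normalization acts approximately as a
global rescaling and the Euclidean ``separation`` between class centers (in
units of ``spread``) remains the single knob controlling classifier
difficulty. This is an explicit emulation, not a claim about the geometry
of any real basecaller's feature space.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classifier import normalize_features
from .motifs import SUPPORTED_MOTIFS, normalize_motif, require_supported_motif

__all__ = [
    "FeatureDistribution",
    "gen_features",
    "gen_training_set",
    "Oligo",
    "oligo_library",
    "LigationDesign",
    "rl_design",
    "sl_design",
    "test1_design",
    "test2_design",
    "TEST2_UNIT",
    "ConcatemerRead",
    "SiteLabel",
    "gen_concatemer_reads",
    "TitrationConfig",
    "SiteSimulation",
    "negbin_coverage",
    "uniform_stoichiometry",
    "gen_site_sim",
]

UNM, MOD = "UNM", "MOD"

_PEDESTAL = 8.0  # pedestal coordinate, in units of spread


def _motif_hash(motif: str) -> int:
    return zlib.crc32(motif.encode())


@dataclass(frozen=True)
class FeatureDistribution:
    """Class-conditional Gaussian feature model for one motif.

    The UNM center is a small random vector plus the pedestal on coordinate
    0; the MOD center sits at Euclidean distance ``separation * spread``
    along a random unit direction orthogonal to the pedestal coordinate.
    Centers are a deterministic function of (motif, center_seed).
    """

    motif: str
    n_features: int = 768
    spread: float = 1.0
    separation: float = 4.0
    center_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "motif", require_supported_motif(self.motif))
        if self.n_features < 2:
            raise ValueError("n_features must be at least 2")
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")

    def center(self, label: str) -> np.ndarray:
        rng = np.random.default_rng([self.center_seed, _motif_hash(self.motif)])
        base = rng.normal(0.0, 0.5 * self.spread, self.n_features)
        base[0] = _PEDESTAL * self.spread
        if label == UNM:
            return base
        if label == MOD:
            u = rng.standard_normal(self.n_features)
            u[0] = 0.0
            u /= np.linalg.norm(u)
            return base + self.separation * self.spread * u
        raise ValueError(f"label must be {UNM!r} or {MOD!r}, got {label!r}")


def _coerce_label(label) -> str:
    if label in (UNM, 0, False):
        return UNM
    if label in (MOD, 1, True):
        return MOD
    raise ValueError(f"label must be UNM/MOD (or 0/1), got {label!r}")


def gen_features(
    motif: str,
    label,
    n: int,
    dist: FeatureDistribution | None = None,
    seed: int = 0,
    normalize: bool = True,
) -> np.ndarray:
    """Draw ``n`` feature vectors for one (motif, class), max-abs normalized.

    Returns an array of shape (n, D). ``dist`` defaults to
    ``FeatureDistribution(motif)``; if given, its motif must match.
    """
    canon = require_supported_motif(motif)
    if n < 0:
        raise ValueError("n must be non-negative")
    if dist is None:
        dist = FeatureDistribution(motif=canon)
    elif dist.motif != canon:
        raise ValueError(f"distribution is for {dist.motif}, not {canon}")
    lab = _coerce_label(label)
    rng = np.random.default_rng(seed)
    X = dist.center(lab) + dist.spread * rng.standard_normal((n, dist.n_features))
    return normalize_features(X) if normalize else X


def gen_training_set(
    motif: str,
    n_per_class: int,
    dist: FeatureDistribution | None = None,
    seed: int = 0,
):
    """Balanced labelled sample for one motif: returns (X, y), y=1 for MOD."""
    ss = np.random.SeedSequence([seed, _motif_hash(require_supported_motif(motif))])
    s_unm, s_mod = ss.spawn(2)
    X0 = gen_features(motif, UNM, n_per_class, dist=dist, seed=s_unm)
    X1 = gen_features(motif, MOD, n_per_class, dist=dist, seed=s_mod)
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n_per_class, int), np.ones(n_per_class, int)])
    return X, y


# ---------------------------------------------------------------------------
# Ligated-oligo designs and concatemer reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Oligo:
    """One ligation unit: a short RNA (DNA alphabet) with a central DRACH motif."""

    oligo_id: str
    sequence: str
    motif: str
    central_offset: int  # 0-based offset of the methylatable A in `sequence`
    modified: bool

    def __post_init__(self):
        object.__setattr__(self, "motif", require_supported_motif(self.motif))
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        lo, hi = self.central_offset - 2, self.central_offset + 3
        if not (0 <= lo and hi <= len(seq)):
            raise ValueError("central motif does not fit inside the oligo")
        if seq[lo:hi] != self.motif:
            raise ValueError(
                f"sequence window {seq[lo:hi]} at offset {self.central_offset} "
                f"does not spell motif {self.motif}"
            )


_BASES = np.array(list("ACGT"))

#: 13-mer repeat unit of the periodic benchmark design; GGACT at offset 5,
#: central A at offset 7.
TEST2_UNIT = "CTGCAGGACTTCG"


def _contains_spurious_motif(seq: str, allowed_offsets: set[int]) -> bool:
    for m in SUPPORTED_MOTIFS:
        start = 0
        while True:
            i = seq.find(m, start)
            if i == -1:
                break
            if i not in allowed_offsets:
                return True
            start = i + 1
    return False


def oligo_library(length: int = 21, seed: int = 0) -> dict[str, str]:
    """Deterministic library of one oligo sequence per supported motif.

    Each sequence is ``length`` nt with its motif centered (central A at
    ``length // 2``). Flanks are drawn by rejection sampling so that no
    supported motif appears anywhere except at the designed centers — not
    within an oligo, nor across any junction of any ordered oligo pair
    (including self-ligation), so concatemers contain exactly the designed
    candidate sites.
    """
    if length < 10 or length % 2 == 0:
        raise ValueError("oligo length must be odd and at least 11")
    center = length // 2
    mstart = center - 2
    rng = np.random.default_rng(seed)
    for _attempt in range(1000):
        lib: dict[str, str] = {}
        for motif in SUPPORTED_MOTIFS:
            for _ in range(1000):
                flank = rng.choice(_BASES, size=length)
                seq = "".join(flank[:mstart]) + motif + "".join(flank[mstart + 5:])
                if not _contains_spurious_motif(seq, {mstart}):
                    lib[motif] = seq
                    break
            else:  # pragma: no cover - rejection loop exhausted
                break
        if len(lib) != len(SUPPORTED_MOTIFS):
            continue
        seqs = list(lib.values())
        ok = True
        for a in seqs:
            for b in seqs:
                junction = a[-9:] + b[:9]
                if _contains_spurious_motif(junction, set()):
                    ok = False
        if ok:
            return lib
    raise RuntimeError("could not build a junction-clean oligo library")


@dataclass(frozen=True)
class LigationDesign:
    """Ordered or random description of a synthetic concatemer.

    ``random_order=True`` draws a unit uniformly at each slot (random
    ligation); otherwise units cycle in the given order (splint ligation and
    the periodic benchmark). ``period_nt``/``phase_choices`` are set only
    for the periodic design.
    """

    mode: str
    units: tuple[Oligo, ...]
    random_order: bool = False
    period_nt: int | None = None
    phase_choices: tuple[int, ...] = ()

    def __post_init__(self):
        if not self.units:
            raise ValueError("design needs at least one unit")

    @property
    def min_unit_length(self) -> int:
        return min(len(u.sequence) for u in self.units)


def rl_design(motif: str = "GGACT", modified: bool = True, length: int = 21, seed: int = 0) -> LigationDesign:
    """Random-ligation homopolymer of one oligo (UNM or MOD pool)."""
    canon = require_supported_motif(motif)
    lib = oligo_library(length=length, seed=seed)
    tag = MOD if modified else UNM
    unit = Oligo(f"{canon}_{tag}", lib[canon], canon, length // 2, modified)
    return LigationDesign(mode="RL_homopolymer", units=(unit,), random_order=False)


def sl_design(modified_motifs: Sequence[str] = (), length: int = 21, seed: int = 0) -> LigationDesign:
    """Splint-ligation heteropolymer cycling through all six motif oligos."""
    mods = {require_supported_motif(m) for m in modified_motifs}
    lib = oligo_library(length=length, seed=seed)
    units = tuple(
        Oligo(
            f"{m}_{MOD if m in mods else UNM}",
            lib[m],
            m,
            length // 2,
            m in mods,
        )
        for m in SUPPORTED_MOTIFS
    )
    return LigationDesign(mode="SL_heteropolymer", units=units, random_order=False)


def test1_design(variant: str = "a", length: int = 21, seed: int = 0) -> LigationDesign:
    """Two-motif random-ligation contrast: TGACT vs GGACC oligos.

    Variant "a" carries m6A on the TGACT (UGACU) oligo, variant "b" flips
    the contrast onto GGACC.
    """
    if variant not in ("a", "b"):
        raise ValueError("variant must be 'a' or 'b'")
    lib = oligo_library(length=length, seed=seed)
    mod_motif = "TGACT" if variant == "a" else "GGACC"
    units = tuple(
        Oligo(
            f"{m}_{MOD if m == mod_motif else UNM}",
            lib[m],
            m,
            length // 2,
            m == mod_motif,
        )
        for m in ("TGACT", "GGACC")
    )
    return LigationDesign(mode="TEST1", units=units, random_order=True)


def test2_design() -> LigationDesign:
    """Periodic design: one 13-mer repeated, every second repeat modified.

    The sequence repeats every 13 nt while m6A recurs in 26-nt cycles; a
    read may start on either a modified or an unmodified repeat, giving a
    phase of 0 or 13 nt.
    """
    units = (
        Oligo("GGACT_cycle_MOD", TEST2_UNIT, "GGACT", 7, True),
        Oligo("GGACT_cycle_UNM", TEST2_UNIT, "GGACT", 7, False),
    )
    return LigationDesign(
        mode="TEST2",
        units=units,
        random_order=False,
        period_nt=13,
        phase_choices=(0, 13),
    )


@dataclass(frozen=True)
class SiteLabel:
    """Ground truth for one candidate A on a read."""

    offset: int  # 0-based position of the central A in the read
    motif: str
    modified: bool


@dataclass(frozen=True)
class ConcatemerRead:
    read_id: str
    sequence: str
    unit_ids: tuple[str, ...]
    sites: tuple[SiteLabel, ...]
    phase_nt: int | None = None
    flagged: bool = False


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def gen_concatemer_reads(
    design: LigationDesign,
    n_reads: int,
    read_len_nt: int,
    sub_error_rate: float = 0.0,
    seed: int = 0,
    phase_nt: int | None = None,
) -> list[ConcatemerRead]:
    """Simulate concatemer reads with per-position ground-truth m6A labels.

    Reads are exact unit concatenations truncated to ``read_len_nt``, with
    i.i.d. substitution errors at ``sub_error_rate``. Candidate sites whose
    motif window does not fit in the read are dropped. For the periodic
    design the phase is drawn uniformly from the design's choices unless
    fixed via ``phase_nt``. Reads shorter than one unit carry no candidate
    sites and are flagged.
    """
    if not 0.0 <= sub_error_rate < 0.5:
        raise ValueError("sub_error_rate must be in [0, 0.5)")
    if n_reads < 0 or read_len_nt < 0:
        raise ValueError("n_reads and read_len_nt must be non-negative")
    rng = np.random.default_rng(seed)
    periodic = design.period_nt is not None
    too_short = read_len_nt < design.min_unit_length
    reads: list[ConcatemerRead] = []
    for r in range(n_reads):
        if periodic:
            if phase_nt is not None:
                phase = phase_nt
            else:
                phase = int(rng.choice(design.phase_choices))
            if phase % len(design.units[0].sequence) != 0:
                raise ValueError("phase must be a multiple of the unit length")
            start_unit = phase // len(design.units[0].sequence)
        else:
            phase = None
            start_unit = 0
        units: list[Oligo] = []
        total = 0
        k = start_unit
        while total < read_len_nt:
            if design.random_order:
                unit = design.units[rng.integers(len(design.units))]
            else:
                unit = design.units[k % len(design.units)]
            units.append(unit)
            total += len(unit.sequence)
            k += 1
        seq = "".join(u.sequence for u in units)[:read_len_nt]
        sites: list[SiteLabel] = []
        if not too_short:
            offset = 0
            for u in units:
                a = offset + u.central_offset
                if a - 2 >= 0 and a + 3 <= read_len_nt:
                    sites.append(SiteLabel(a, u.motif, u.modified))
                offset += len(u.sequence)
        reads.append(
            ConcatemerRead(
                read_id=f"{design.mode}_read{r:05d}",
                sequence=_mutate(seq, sub_error_rate, rng),
                unit_ids=tuple(u.oligo_id for u in units),
                sites=tuple(sites),
                phase_nt=phase,
                flagged=too_short,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# Transcriptome-scale site simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TitrationConfig:
    """WT/IVT mixing fraction: each read is drawn from WT with prob f_wt."""

    f_wt: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.f_wt <= 1.0:
            raise ValueError("f_wt must lie in [0, 1]")


def negbin_coverage(mean: float = 100.0, dispersion: float = 10.0) -> Callable:
    """Negative-binomial coverage law with the given mean and shape."""

    def law(rng: np.random.Generator, n: int) -> np.ndarray:
        p = dispersion / (dispersion + mean)
        return rng.negative_binomial(dispersion, p, size=n)

    return law


def uniform_stoichiometry(low: float = 0.0, high: float = 1.0) -> Callable:
    """Uniform law for true site stoichiometries; ``low=0.1`` mimics assays
    that do not report values below 10%."""

    def law(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(low, high, size=n)

    return law


@dataclass
class SiteSimulation:
    """Output of :func:`gen_site_sim`.

    ``sites`` holds the ground truth (contig, position, strand, motif,
    s_orig, coverage); ``reads`` one row per simulated read-site observation
    with its true modification label; ``alignments`` the matching minimal
    alignment records (read_id, contig, pos, strand, mapq, group_id).
    """

    sites: pd.DataFrame
    reads: pd.DataFrame
    alignments: pd.DataFrame
    f_wt: float
    ko_factor: float | None = None


def gen_site_sim(
    n_sites: int,
    coverage_law: Callable | int | None = None,
    s_law: Callable | None = None,
    titration: TitrationConfig | None = None,
    ko_factor: float | None = None,
    seed: int = 0,
    contig: str = "chr1",
    contig_length: int = 1_000_000,
    low_mapq_fraction: float = 0.0,
    n_groups: int = 1,
) -> SiteSimulation:
    """Simulate a transcriptome-scale set of m6A sites and their reads.

    Each site gets a true stoichiometry ``s_orig`` from ``s_law`` (default
    Uniform(0,1)) and a coverage from ``coverage_law`` (an int for fixed
    coverage; default negative binomial with mean 100). Each read at a site
    is modified independently with probability ``f_wt * s_orig`` — the
    expected dilution of a WT/IVT mixture with WT fraction ``f_wt`` — or,
    when ``ko_factor`` is given, with probability ``ko_factor * s_orig``
    (knockout arm, no IVT mixing). Alignment records carry mapq 60 except
    for a ``low_mapq_fraction`` of reads with mapq drawn below 50; reads are
    assigned round-robin to ``n_groups`` transcript groups.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be at least 1")
    titration = titration or TitrationConfig()
    if ko_factor is not None and not 0.0 <= ko_factor <= 1.0:
        raise ValueError("ko_factor must lie in [0, 1]")
    rng = np.random.default_rng([seed, titration.seed])
    if coverage_law is None:
        coverage_law = negbin_coverage()
    if isinstance(coverage_law, (int, np.integer)):
        fixed = int(coverage_law)
        coverage_law = lambda r, n: np.full(n, fixed, dtype=int)  # noqa: E731
    if s_law is None:
        s_law = uniform_stoichiometry()

    positions = np.sort(rng.choice(contig_length, size=n_sites, replace=False))
    strands = rng.choice(["+", "-"], size=n_sites)
    motifs = rng.choice(SUPPORTED_MOTIFS, size=n_sites)
    s_orig = s_law(rng, n_sites)
    coverage = np.asarray(coverage_law(rng, n_sites), dtype=int)

    sites = pd.DataFrame(
        {
            "contig": contig,
            "position": positions,
            "strand": strands,
            "motif": motifs,
            "s_orig": s_orig,
            "coverage": coverage,
        }
    )

    p_mod = (ko_factor if ko_factor is not None else titration.f_wt) * s_orig
    rows_site = np.repeat(np.arange(n_sites), coverage)
    n_reads = rows_site.size
    modified = rng.random(n_reads) < p_mod[rows_site]
    mapq = np.full(n_reads, 60, dtype=int)
    if low_mapq_fraction > 0:
        low = rng.random(n_reads) < low_mapq_fraction
        mapq[low] = rng.integers(0, 50, size=int(low.sum()))
    read_ids = np.array([f"read{j:07d}" for j in range(n_reads)])
    groups = np.array([f"tx{j % n_groups}" for j in range(n_reads)])

    reads = pd.DataFrame(
        {
            "read_id": read_ids,
            "contig": contig,
            "position": positions[rows_site],
            "strand": strands[rows_site],
            "motif": motifs[rows_site],
            "group_id": groups,
            "modified": modified,
            "mapq": mapq,
        }
    )
    alignments = reads[["read_id", "contig", "position", "strand", "mapq", "group_id"]].rename(
        columns={"position": "pos"}
    )
    return SiteSimulation(
        sites=sites,
        reads=reads,
        alignments=alignments,
        f_wt=titration.f_wt,
        ko_factor=ko_factor,
    )
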