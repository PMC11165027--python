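"""Synthetic immunoglobulin V-gene alleles and mutated clonal repertoires.

This module builds the ground-truth world that the rest of the pipeline
analyses: germline-like V alleles segmented into IMGT-style subregions
(L-intron-L, FW1, CDR1, FW2, CDR2, FW3) carrying AGCT hotspot motifs, a
per-site mutation-rate model with planted E-box suppression and
pyrimidine-dimer (PyPy) enhancement effects, and Bernoulli-mutated clonal
repertoires with one representative sequence per clonal group.

The rate model, per site:

* non-hotspot A/T sites mutate at ``base_rate_at``; non-hotspot C/G sites
  at ``base_rate_cg``;
* C/G sites inside a WRCH/DGYW AID hotspot mutate at ``hotspot_rate``;
* the G and C of an AGCT lying inside a CAGCTG E-box context are
  multiplied by ``ebox_multiplier`` (suppression when < 1);
* AGCT sites then receive an additive PyPy effect on the logit scale,
  ``pypy_slope`` per pyrimidine dimer in the 6 nt immediately upstream of
  the AGCT's A;
* finally a multiplicative lognormal noise factor is applied and rates
  are clipped to [0, 1].

All three public operations are pure functions of their arguments
(including the seed): same call, byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

SUBREGION_ORDER: tuple[str, ...] = ("L-intron-L", "FW1", "CDR1", "FW2", "CDR2", "FW3")

#: Plausible IMGT-like subregion lengths (nt).  Only the FW1 anchor — the
#: conserved AGCT at V-segment positions 8-11, inside a CAGCTG at 7-12 —
#: is load-bearing downstream.
DEFAULT_LENGTHS: dict[str, int] = {
    "L-intron-L": 60,
    "FW1": 78,
    "CDR1": 24,
    "FW2": 51,
    "CDR2": 24,
    "FW3": 114,
}

#: Default number of extra AGCT motifs planted per subregion (FW1 gets its
#: anchor AGCT separately).
DEFAULT_AGCT_DENSITY: dict[str, int] = {"CDR1": 1, "FW2": 1, "CDR2": 1, "FW3": 2}

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype="S1")
_PYRIMIDINES = frozenset("CT")

# index lookup table: ASCII code -> 0..3, -1 for non-ACGT
_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i

# alternatives for a uniform substitution draw, per germline base index
_ALT = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]], dtype=np.int8)

_W = frozenset("AT")
_R = frozenset("AG")
_H = frozenset("ACT")
_D = frozenset("AGT")
_Y = frozenset("CT")


def _seq_to_idx(sequence: str) -> np.ndarray:
    idx = _LUT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (idx < 0).any():
        bad = sorted(set(sequence) - set(BASES))
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")
    return idx.astype(np.intp)


@dataclass(frozen=True)
class VAllele:
    """A germline V-gene sequence with named subregion boundaries.

    Boundaries are 1-based inclusive ``(name, start, end)`` intervals that
    tile the sequence in the fixed order L-intron-L, FW1, ..., FW3.  FW1
    starts the V segment, so "V-segment position p" maps to sequence
    position ``fw1_start + p - 1``.
    """

    allele_id: str
    family: str
    sequence: str
    boundaries: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        _seq_to_idx(self.sequence)  # validates the alphabet
        names = tuple(b[0] for b in self.boundaries)
        if names != SUBREGION_ORDER[: len(names)]:
            raise ValueError(f"subregions must appear in order {SUBREGION_ORDER}, got {names}")
        cursor = 1
        for name, start, end in self.boundaries:
            if start != cursor or end < start:
                raise ValueError(f"boundaries are not contiguous at {name}: ({start}, {end})")
            cursor = end + 1
        if cursor != len(self.sequence) + 1:
            raise ValueError("boundaries do not cover the full sequence")

    @property
    def fw1_start(self) -> int:
        """1-based sequence position where the V segment (FW1) begins."""
        for name, start, _ in self.boundaries:
            if name == "FW1":
                return start
        raise ValueError("allele has no FW1 subregion")

    def v_position(self, p: int) -> int:
        """Map a 1-based V-segment position to a 1-based sequence position."""
        return self.fw1_start + p - 1

    def subregion_of(self, position: int) -> str:
        """Name of the subregion containing a 1-based sequence position."""
        for name, start, end in self.boundaries:
            if start <= position <= end:
                return name
        raise ValueError(f"position {position} outside allele {self.allele_id} (1..{len(self.sequence)})")

    def subsequence(self, name: str) -> str:
        for n, start, end in self.boundaries:
            if n == name:
                return self.sequence[start - 1 : end]
        raise KeyError(name)


@dataclass(frozen=True)
class RateParams:
    """Parameters of the per-site mutation-rate model (see module docstring)."""

    base_rate_at: float = 0.005
    base_rate_cg: float = 0.01
    hotspot_rate: float = 0.15
    ebox_multiplier: float = 0.3
    pypy_slope: float = 0.15
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_rate_at", "base_rate_cg", "hotspot_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.ebox_multiplier <= 1.0:
            raise ValueError(f"ebox_multiplier must be in (0, 1], got {self.ebox_multiplier}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SiteRateMap:
    """True per-site per-clone mutation probabilities for one allele."""

    allele_id: str
    rates: np.ndarray

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        if rates.ndim != 1:
            raise ValueError("rates must be a 1-D array")
        if (rates < 0).any() or (rates > 1).any():
            raise ValueError("rates must lie in [0, 1]")
        object.__setattr__(self, "rates", rates)


@dataclass(frozen=True)
class Repertoire:
    """Mutated clonal sequences, one representative per clonal group.

    Sequences are stored as an ``(n_clones, L)`` byte matrix; ``clones``
    materialises them as strings.
    """

    allele_id: str
    seqs: np.ndarray

    def __post_init__(self) -> None:
        seqs = np.asarray(self.seqs, dtype="S1")
        if seqs.ndim != 2:
            raise ValueError("seqs must be a 2-D (n_clones, L) byte matrix")
        object.__setattr__(self, "seqs", seqs)

    @property
    def n_clones(self) -> int:
        return self.seqs.shape[0]

    @property
    def clones(self) -> list[str]:
        return [row.tobytes().decode("ascii") for row in self.seqs]

    @classmethod
    def from_strings(cls, allele_id: str, clones: list[str]) -> "Repertoire":
        if clones and len({len(c) for c in clones}) > 1:
            raise ValueError("clones must all have the same length")
        mat = np.frombuffer("".join(clones).encode("ascii"), dtype="S1")
        n = len(clones)
        mat = mat.reshape(n, -1) if n else mat.reshape(0, 0)
        return cls(allele_id, mat)


def hotspot_mask(sequence: str) -> np.ndarray:
    """Boolean mask of AID-hotspot C/G sites.

    WRCH on the top strand marks its C; DGYW (the reverse complement read
    on the top strand) marks its G, i.e. the C deaminated on the bottom
    strand.  AGCT, being palindromic, marks both central bases.
    """
    s = sequence
    mask = np.zeros(len(s), dtype=bool)
    for i in range(len(s) - 3):
        w = s[i : i + 4]
        if w[0] in _W and w[1] in _R and w[2] == "C" and w[3] in _H:
            mask[i + 2] = True
        if w[0] in _D and w[1] == "G" and w[2] in _Y and w[3] in _W:
            mask[i + 1] = True
    return mask


def agct_positions(sequence: str) -> list[int]:
    """0-based start positions of every AGCT occurrence."""
    out, start = [], 0
    while True:
        i = sequence.find("AGCT", start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def count_pypy(window: str, overlapping: bool = True) -> int:
    """Number of pyrimidine-dimer (C/T followed by C/T) pairs in a window."""
    step = 1 if overlapping else 2
    return sum(
        window[i] in _PYRIMIDINES and window[i + 1] in _PYRIMIDINES
        for i in range(0, len(window) - 1, step)
    )


def _validate_length_spec(length_spec: dict[str, int] | None) -> dict[str, int]:
    lengths = dict(DEFAULT_LENGTHS)
    if length_spec:
        unknown = set(length_spec) - set(SUBREGION_ORDER)
        if unknown:
            raise ValueError(f"unknown subregions in length_spec: {sorted(unknown)}")
        lengths.update(length_spec)
    for name, n in lengths.items():
        if not isinstance(n, (int, np.integer)) or n <= 0:
            raise ValueError(f"length of {name} must be a positive integer, got {n!r}")
    if lengths["FW1"] < 18:
        raise ValueError("FW1 must be at least 18 nt to hold the anchored CAGCTG")
    return lengths


def generate_alleles(
    n_alleles: int,
    length_spec: dict[str, int] | None = None,
    ebox_fw1_prob: float = 0.8,
    agct_density: dict[str, int] | None = None,
    seed: int = 0,
) -> list[VAllele]:
    """Generate germline-like V alleles with planted AGCT motifs.

    Every allele carries an AGCT at V-segment positions 8-11.  With
    probability ``ebox_fw1_prob`` its flanks are fixed to C (V position 7)
    and G (V position 12), completing a CAGCTG E-box; otherwise the flank
    pair is drawn uniformly from the 15 non-(C, G) combinations.
    Additional AGCTs are planted per ``agct_density`` (subregion -> count)
    at non-overlapping interior positions with random flanks.
    """
    if not isinstance(n_alleles, (int, np.integer)) or n_alleles < 0:
        raise ValueError(f"n_alleles must be a non-negative integer, got {n_alleles!r}")
    if not 0.0 <= ebox_fw1_prob <= 1.0:
        raise ValueError("ebox_fw1_prob must be in [0, 1]")
    lengths = _validate_length_spec(length_spec)
    density = DEFAULT_AGCT_DENSITY if agct_density is None else agct_density
    if set(density) - set(SUBREGION_ORDER):
        raise ValueError(f"unknown subregions in agct_density: {sorted(set(density) - set(SUBREGION_ORDER))}")

    rng = np.random.default_rng(seed)
    boundaries, cursor = [], 1
    for name in SUBREGION_ORDER:
        boundaries.append((name, cursor, cursor + lengths[name] - 1))
        cursor += lengths[name]
    boundaries = tuple(boundaries)
    total_len = cursor - 1
    region_span = {name: (start, end) for name, start, end in boundaries}

    alleles = []
    for i in range(n_alleles):
        seq = rng.choice(list(BASES), size=total_len).tolist()

        # extra AGCTs, interior to their subregion with a 6-nt margin so
        # both the flanks and the upstream PyPy window stay in-region
        for name, count in density.items():
            start, end = region_span[name]
            lo, hi = start - 1 + 6, end - 1 - 3 - 6  # 0-based candidate starts
            if hi < lo:
                raise ValueError(f"subregion {name} too short to plant an AGCT with margins")
            placed: list[int] = []
            attempts = 0
            while len(placed) < count:
                attempts += 1
                if attempts > 1000:
                    raise ValueError(f"cannot place {count} non-overlapping AGCTs in {name}")
                p = int(rng.integers(lo, hi + 1))
                if all(abs(p - q) >= 10 for q in placed):
                    placed.append(p)
                    seq[p : p + 4] = list("AGCT")

        # FW1 anchor: AGCT at V positions 8-11 (CAGCTG at 7-12 with
        # probability ebox_fw1_prob)
        fw1_start0 = region_span["FW1"][0] - 1
        seq[fw1_start0 + 7 : fw1_start0 + 11] = list("AGCT")
        if rng.random() < ebox_fw1_prob:
            flank5, flank3 = "C", "G"
        else:
            while True:
                flank5, flank3 = rng.choice(list(BASES), size=2)
                if not (flank5 == "C" and flank3 == "G"):
                    break
        seq[fw1_start0 + 6] = flank5
        seq[fw1_start0 + 11] = flank3

        family = f"IGHV{i % 7 + 1}"
        alleles.append(
            VAllele(
                allele_id=f"{family}-S{i + 1}*01",
                family=family,
                sequence="".join(seq),
                boundaries=boundaries,
            )
        )
    return alleles


def assign_true_site_rates(allele: VAllele, params: RateParams) -> SiteRateMap:
    """Assign the ground-truth per-site mutation probability for an allele.

    Deterministic given ``params.seed`` (which drives only the lognormal
    noise draw).
    """
    seq = allele.sequence
    idx = _seq_to_idx(seq)
    rates = np.where(
        (idx == 0) | (idx == 3), params.base_rate_at, params.base_rate_cg
    ).astype(float)
    hs = hotspot_mask(seq)
    rates[hs] = params.hotspot_rate

    for a in agct_positions(seq):
        sites = [a + 1, a + 2]  # the G and the C of AGCT
        ebox = a >= 1 and a + 4 < len(seq) and seq[a - 1] == "C" and seq[a + 4] == "G"
        if ebox:
            for s in sites:
                rates[s] *= params.ebox_multiplier
        if params.pypy_slope != 0.0:
            npp = count_pypy(seq[max(0, a - 6) : a])
            if npp:
                for s in sites:
                    rates[s] = float(expit(logit(rates[s]) + params.pypy_slope * npp))

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        rates *= rng.lognormal(mean=0.0, sigma=params.noise_sd, size=rates.size)

    return SiteRateMap(allele.allele_id, np.clip(rates, 0.0, 1.0))


def simulate_repertoire(
    allele: VAllele, rates: SiteRateMap, n_clones: int, seed: int = 0
) -> Repertoire:
    """Draw a repertoire of clonally independent mutated sequences.

    Each site of each clone mutates independently with probability
    ``rates[site]``; a mutated base is replaced uniformly by one of the
    three alternatives.  No indels, no selection, no clonal phylogeny.
    """
    if not isinstance(n_clones, (int, np.integer)) or n_clones < 0:
        raise ValueError(f"n_clones must be a non-negative integer, got {n_clones!r}")
    if len(rates.rates) != len(allele.sequence):
        raise ValueError(
            f"rate map length {len(rates.rates)} does not match allele length {len(allele.sequence)}"
        )
    rng = np.random.default_rng(seed)
    L = len(allele.sequence)
    base_idx = _seq_to_idx(allele.sequence)
    mutated = rng.random((n_clones, L)) < rates.rates[None, :]
    alt_draw = rng.integers(0, 3, size=(n_clones, L))
    new_idx = _ALT[base_idx[None, :], alt_draw]
    germ_row = _BASE_ARR[base_idx]
    seqs = np.where(mutated, _BASE_ARR[new_idx], germ_row[None, :])
    return Repertoire(allele.allele_id, seqs)


def expected_rate(params: RateParams, *, hotspot: bool, ebox: bool = False, pypy: int = 0) -> float:
    """Closed-form expected realised rate for one site class (pre-clipping).

    Multiplicative lognormal noise with log-sd sigma has mean exp(sigma^2/2),
    so the expectation is the deterministic rate times that factor.
    """
    r = params.hotspot_rate if hotspot else params.base_rate_cg
    if ebox:
        r *= params.ebox_multiplier
    if pypy and params.pypy_slope != 0.0:
        r = float(expit(logit(r) + params.pypy_slope * pypy))
    return r * math.exp(params.noise_sd**2 / 2.0)
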