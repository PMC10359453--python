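"""Planted-truth synthetic data for every pipeline stage.

Three generators, all fully reproducible from integer seeds:

* two-subfamily protein alignments with signature residues (by default the
  UdgX-type Q53/R107/H109 against the canonical family-4 A53/P107/N109),
  tunable per-position conservation, independent background columns, and
  optionally coupled column pairs — a star-topology emulation of the large
  similarity-search alignments used for conservation/coevolution profiling
  (no phylogenetic correlation, matching the raw-count analysis it feeds);
* Michaelis–Menten rate datasets and initial-rate time courses with
  multiplicative Gaussian noise (roughly constant CV across substrate
  levels, as in gel-quantified assays);
* toy C-alpha traces for superposition tests.

Every generator returns, or embeds, a truth record so that downstream
recovery tests compare against planted ground truth, never against the
method under test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._alphabet import AMINO_ACIDS
from .exceptions import ConfigError
from .kinetics import DEFAULT_S_GRID_NM, KineticsDataset, TimeCourse
from .msa import Msa
from .structure import Atom, Structure

__all__ = [
    "MsaTruth",
    "KineticsTruth",
    "generate_msa",
    "generate_kinetics",
    "generate_timecourses",
    "helix_ca_trace",
    "jitter_structure",
    "apply_rigid",
]

_AA = np.array(list(AMINO_ACIDS))


# ---------------------------------------------------------------------------
# alignment generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MsaTruth:
    """Ground-truth description of a two-subfamily synthetic alignment.

    Defaults emulate the study conditions of the UdgX/family-4 analysis:
    2000 sequences, an even subfamily split, subfamily-defining residues at
    reference positions 53/107/109 planted at conservation 0.99, and
    background columns whose consensus residue appears with probability
    0.4 (low enough that no background column ever passes a 0.95
    conservation filter at these sample sizes).
    """

    n_sequences: int = 2000
    length: int = 200
    subfamily_fraction: float = 0.5
    signature_a: Mapping[int, str] = field(
        default_factory=lambda: {53: "Q", 107: "R", 109: "H"}
    )
    signature_b: Mapping[int, str] = field(
        default_factory=lambda: {53: "A", 107: "P", 109: "N"}
    )
    conservation_level: float | Mapping[int, float] = 0.99
    background_consensus_p: float = 0.4
    coupled_pairs: tuple[tuple[int, int, float], ...] = ()
    ref_id: str = "MsmUdgX"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.length < 1:
            raise ConfigError("n_sequences and length must be >= 1")
        if not 0.0 <= self.subfamily_fraction <= 1.0:
            raise ConfigError("subfamily_fraction must be in [0, 1]")
        if not 0.0 < self.background_consensus_p < 1.0:
            raise ConfigError("background_consensus_p must be in (0, 1)")
        if set(self.signature_a) != set(self.signature_b):
            raise ConfigError("signature_a and signature_b must cover the same positions")
        planted = set(self.signature_a)
        for pos in planted:
            if not 1 <= pos <= self.length:
                raise ConfigError(f"signature position {pos} outside 1..{self.length}")
        differing = {p for p in planted if self.signature_a[p] != self.signature_b[p]}
        for pa, pb, prob in self.coupled_pairs:
            if not 0.5 <= prob <= 1.0:
                raise ConfigError(f"coupling probability {prob} outside [0.5, 1]")
            for p in (pa, pb):
                if not 1 <= p <= self.length:
                    raise ConfigError(f"coupled position {p} outside 1..{self.length}")
                if p in differing:
                    raise ConfigError(
                        f"position {p} is both coupled and a subfamily-differing signature"
                    )

    def conservation_at(self, pos: int) -> float:
        if isinstance(self.conservation_level, Mapping):
            return float(self.conservation_level.get(pos, 0.99))
        return float(self.conservation_level)


def _fill_consensus_or_other(
    rng: np.random.Generator, n: int, consensus: str, p: float
) -> np.ndarray:
    """Draw n characters: *consensus* with probability p, else uniform others."""
    out = np.full(n, consensus, dtype="<U1")
    miss = rng.random(n) >= p
    k = int(miss.sum())
    if k:
        others = _AA[_AA != consensus]
        out[miss] = others[rng.integers(0, len(others), size=k)]
    return out


def generate_msa(truth: MsaTruth) -> tuple[Msa, dict]:
    """Generate a gap-free two-subfamily alignment plus its truth record.

    The first record is the reference sequence (``truth.ref_id``): a
    deterministic subfamily-A consensus sequence, so alignment columns and
    reference positions coincide.  Each simulated sequence is assigned to
    subfamily A with probability ``subfamily_fraction``; planted positions
    carry the subfamily residue with their conservation level, background
    positions carry a column-specific consensus residue with probability
    ``background_consensus_p``, and coupled pairs draw a shared two-state
    indicator whose states match with the pair's coupling probability.
    """
    rng = np.random.default_rng(truth.seed)
    n, length = truth.n_sequences, truth.length
    planted = dict(truth.signature_a)
    coupled_positions = {p for pa, pb, _ in truth.coupled_pairs for p in (pa, pb)}

    # column-specific background consensus residues (also used at coupled columns)
    bg_consensus = _AA[rng.integers(0, len(_AA), size=length)]
    # a distinct alternative residue per coupled column
    coupled_alt: dict[int, str] = {}
    for p in sorted(coupled_positions):
        others = _AA[_AA != bg_consensus[p - 1]]
        coupled_alt[p] = str(others[rng.integers(0, len(others))])

    in_a = rng.random(n) < truth.subfamily_fraction

    chars = np.empty((n, length), dtype="<U1")
    for col in range(1, length + 1):
        j = col - 1
        if col in planted:
            c = truth.conservation_at(col)
            col_chars = np.empty(n, dtype="<U1")
            for is_a, sig in ((True, truth.signature_a), (False, truth.signature_b)):
                mask = in_a == is_a
                k = int(mask.sum())
                if k:
                    col_chars[mask] = _fill_consensus_or_other(rng, k, sig[col], c)
            chars[:, j] = col_chars
        elif col in coupled_positions:
            chars[:, j] = ""  # filled below, jointly per pair
        else:
            chars[:, j] = _fill_consensus_or_other(
                rng, n, str(bg_consensus[j]), truth.background_consensus_p
            )

    for pa, pb, prob in truth.coupled_pairs:
        state_a = rng.random(n) < 0.5
        match = rng.random(n) < prob
        state_b = np.where(match, state_a, ~state_a)
        for pos, state in ((pa, state_a), (pb, state_b)):
            cons, alt = str(bg_consensus[pos - 1]), coupled_alt[pos]
            chars[:, pos - 1] = np.where(state, cons, alt)

    # deterministic subfamily-A consensus reference sequence
    ref = bg_consensus.copy()
    for pos, res in planted.items():
        ref[pos - 1] = res

    ids = [truth.ref_id] + [f"seq{i:05d}" for i in range(n)]
    seqs = ["".join(ref)] + ["".join(row) for row in chars]
    msa = Msa(tuple(ids), tuple(seqs))

    record = {
        "seed": truth.seed,
        "ref_id": truth.ref_id,
        "n_generated": n,
        "subfamily": {
            truth.ref_id: "A",
            **{ids[i + 1]: ("A" if in_a[i] else "B") for i in range(n)},
        },
        "signature_a": {int(p): r for p, r in truth.signature_a.items()},
        "signature_b": {int(p): r for p, r in truth.signature_b.items()},
        "planted_unique": sorted(
            int(p) for p in planted if truth.signature_a[p] != truth.signature_b[p]
        ),
        "conservation_level": (
            dict(truth.conservation_level)
            if isinstance(truth.conservation_level, Mapping)
            else truth.conservation_level
        ),
        "background_consensus": {i + 1: str(r) for i, r in enumerate(bg_consensus)},
        "coupled_pairs": [
            {"pos_a": int(pa), "pos_b": int(pb), "coupling": float(pr)}
            for pa, pb, pr in truth.coupled_pairs
        ],
    }
    return msa, record


# ---------------------------------------------------------------------------
# kinetics generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticsTruth:
    """Ground truth for simulated Michaelis–Menten assays.

    Defaults follow the uracil-excision assay design: the 60–3010 nM
    label-dilution substrate grid, [Et] = 200 nM, and noise-free rates.
    ``noise_sd_fraction`` is the SD of multiplicative Gaussian noise on v.
    """

    vmax: float = 22.97       # nM min^-1
    km: float = 174.76        # nM
    et: float = 200.0         # nM
    s_grid: tuple[float, ...] = DEFAULT_S_GRID_NM
    noise_sd_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0 or self.et <= 0:
            raise ConfigError("vmax, km and et must be positive")
        if len(set(self.s_grid)) != len(self.s_grid) or any(s <= 0 for s in self.s_grid):
            raise ConfigError("s_grid must be distinct positive concentrations")
        if not 0.0 <= self.noise_sd_fraction < 1.0:
            raise ConfigError("noise_sd_fraction must be in [0, 1)")

    def rate(self, s: np.ndarray | float) -> np.ndarray | float:
        return self.vmax * np.asarray(s, dtype=float) / (self.km + np.asarray(s, dtype=float))


def _noisy_rates(truth: KineticsTruth, rng: np.random.Generator) -> np.ndarray:
    s = np.asarray(truth.s_grid, dtype=float)
    v = np.asarray(truth.rate(s), dtype=float)
    if truth.noise_sd_fraction == 0.0:
        return v
    out = v * (1.0 + rng.normal(0.0, truth.noise_sd_fraction, size=v.shape))
    # truncate to positive rates by redrawing the offending noise terms
    for _ in range(1000):
        bad = out <= 0
        if not bad.any():
            break
        out[bad] = v[bad] * (1.0 + rng.normal(0.0, truth.noise_sd_fraction, size=int(bad.sum())))
    return out


def generate_kinetics(truth: KineticsTruth) -> KineticsDataset:
    """(S, v) dataset: v = Vmax S/(Km+S) times multiplicative noise, v > 0."""
    rng = np.random.default_rng(truth.seed)
    return KineticsDataset(tuple(truth.s_grid), tuple(_noisy_rates(truth, rng)))


def generate_timecourses(
    truth: KineticsTruth, times: Sequence[float] = (2.0, 4.0, 6.0, 8.0)
) -> list[TimeCourse]:
    """One product-vs-time course per substrate level, in the linear regime.

    product(t) = v(S) t with per-point multiplicative noise.  Courses where
    the product exceeds 10% of the substrate leave the initial-rate regime
    and trigger a warning.
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ConfigError("times must be strictly increasing")
    rng = np.random.default_rng(truth.seed)
    out = []
    for s in truth.s_grid:
        v = float(truth.rate(s))
        prod = v * t
        if truth.noise_sd_fraction > 0.0:
            prod = prod * (1.0 + rng.normal(0.0, truth.noise_sd_fraction, size=t.shape))
            prod = np.clip(prod, 0.0, None)
        if prod.max() > 0.1 * s:
            warnings.warn(
                f"S={s:g} nM: product reaches {prod.max():.3g} nM (> 10% of S); "
                "initial-rate assumption strained",
                stacklevel=2,
            )
        out.append(TimeCourse(tuple(t), tuple(prod), substrate_nM=float(s)))
    return out


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

def helix_ca_trace(n_residues: int = 100, chain: str = "A") -> Structure:
    """Ideal alpha-helical C-alpha trace (2.3 Å radius, 1.5 Å rise, 100°/res)."""
    if n_residues < 1:
        raise ValueError("need at least one residue")
    atoms = []
    for i in range(n_residues):
        theta = np.deg2rad(100.0 * i)
        xyz = (2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i)
        atoms.append(
            Atom(chain=chain, residue_number=i + 1, residue_name="ALA", name="CA",
                 xyz=tuple(float(c) for c in xyz), element="C")
        )
    return Structure(atoms=tuple(atoms))


def jitter_structure(s: Structure, sigma_per_axis: float, seed: int = 0) -> Structure:
    """Add isotropic Gaussian noise (Å per axis) to every atom position."""
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma_per_axis, size=(s.n_atoms, 3))
    atoms = tuple(
        Atom(chain=a.chain, residue_number=a.residue_number, residue_name=a.residue_name,
             name=a.name, xyz=tuple(float(c) for c in (np.array(a.xyz) + d)),
             altloc=a.altloc, occupancy=a.occupancy, element=a.element)
        for a, d in zip(s.atoms, noise)
    )
    return Structure(atoms=atoms, model_id=s.model_id)


def apply_rigid(
    s: Structure, rotation: np.ndarray, translation: Sequence[float]
) -> Structure:
    """Apply the rigid transform x -> R x + t to every atom."""
    r = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    atoms = tuple(
        Atom(chain=a.chain, residue_number=a.residue_number, residue_name=a.residue_name,
             name=a.name, xyz=tuple(float(c) for c in (r @ np.array(a.xyz) + t)),
             altloc=a.altloc, occupancy=a.occupancy, element=a.element)
        for a in s.atoms
    )
    return Structure(atoms=atoms, model_id=s.model_id)
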