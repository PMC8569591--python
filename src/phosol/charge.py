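"""Residue charge model, local charge density and net charge per residue (NCPR).

Side-chain charges at physiological pH (7.4) follow a simple integer/half-integer
scheme: D/E carry -1, K/R carry +1, H carries +0.5, and phosphorylated S/T/Y
carry -2 (phosphate at pH 7.4); every other residue, including the ambiguity
codes B/Z/X/U/O, is neutral. Local charge density is the mean charge over a
sliding window (default 21 residues) enumerated from the C-terminus toward the
N-terminus; NCPR is the charge sum divided by protein length.

Phosphorylation states let the same sequence be profiled hypo-phosphorylated
(no sites), with an observed site list (e.g. from middle-down MS), or
hyper-phosphorylated (every S/T/Y, optionally restricted to a region such as
an RS domain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STANDARD_RESIDUES",
    "AMBIGUOUS_RESIDUES",
    "PHOSPHO_ACCEPTORS",
    "ProteinRecord",
    "PhosphoSiteSet",
    "PhosphoState",
    "ChargeProfile",
    "ProteomeChargeSummary",
    "residue_charge",
    "charge_profile",
    "ncpr",
    "phospho_variants",
    "proteome_charge_summary",
]

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_RESIDUES = frozenset("BZXUO")  # treated as neutral
ALPHABET = STANDARD_RESIDUES | AMBIGUOUS_RESIDUES
PHOSPHO_ACCEPTORS = frozenset("STY")

_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5}

DEFAULT_WINDOW = 21


class AlphabetError(ValueError):
    """Sequence or residue outside the accepted amino-acid alphabet."""


def residue_charge(aa: str, phosphorylated: bool = False) -> float:
    """Charge of a single residue at pH 7.4.

    Parameters
    ----------
    aa:
        One-letter residue code (case-insensitive). Stops ('*') and gap
        characters are rejected.
    phosphorylated:
        If true, ``aa`` must be S, T or Y and the returned charge is -2.
    """
    if len(aa) != 1:
        raise AlphabetError(f"expected a single residue character, got {aa!r}")
    aa = aa.upper()
    if aa not in ALPHABET:
        raise AlphabetError(f"unknown residue {aa!r}")
    if phosphorylated:
        if aa not in PHOSPHO_ACCEPTORS:
            raise ValueError(f"residue {aa!r} cannot be phosphorylated (S/T/Y only)")
        return -2.0
    return _CHARGE.get(aa, 0.0)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession and optional gene symbol."""

    id: str
    sequence: str
    gene_symbol: Optional[str] = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(seq) - ALPHABET
        if bad:
            raise AlphabetError(
                f"{self.id}: invalid characters {sorted(bad)!r} in sequence"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def sty_positions(self) -> frozenset[int]:
        """1-based positions of all phospho-acceptor (S/T/Y) residues."""
        return frozenset(
            i + 1 for i, aa in enumerate(self.sequence) if aa in PHOSPHO_ACCEPTORS
        )


@dataclass(frozen=True)
class PhosphoSiteSet:
    """Observed phosphosites of one protein as 1-based residue positions."""

    protein_id: str
    positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", frozenset(int(p) for p in self.positions))
        if any(p < 1 for p in self.positions):
            raise ValueError(f"{self.protein_id}: positions must be 1-based (>= 1)")

    def validate_against(self, record: ProteinRecord) -> None:
        for p in self.positions:
            if p > len(record):
                raise ValueError(
                    f"{self.protein_id}: site position {p} beyond length {len(record)}"
                )
            aa = record.sequence[p - 1]
            if aa not in PHOSPHO_ACCEPTORS:
                raise ValueError(
                    f"{self.protein_id}: residue {aa} at position {p} is not S/T/Y"
                )


@dataclass(frozen=True)
class PhosphoState:
    """Which S/T/Y residues count as phosphorylated.

    ``kind`` is one of ``hypo`` (none), ``observed`` (the supplied site set) or
    ``hyper`` (every S/T/Y). ``region`` optionally restricts the effective sites
    to a 1-based inclusive interval, e.g. an RS domain.
    """

    kind: str = "hypo"
    region: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("hypo", "observed", "hyper"):
            raise ValueError(f"unknown phospho state kind {self.kind!r}")
        if self.region is not None:
            lo, hi = self.region
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid region {self.region!r}")

    def effective_sites(
        self, record: ProteinRecord, sites: Optional[PhosphoSiteSet] = None
    ) -> frozenset[int]:
        if self.kind == "hypo":
            base: frozenset[int] = frozenset()
        elif self.kind == "observed":
            if sites is None:
                base = frozenset()
            else:
                sites.validate_against(record)
                base = sites.positions
        else:  # hyper
            base = record.sty_positions()
        if self.region is not None:
            lo, hi = self.region
            base = frozenset(p for p in base if lo <= p <= hi)
        return base


HYPO = PhosphoState("hypo")


@dataclass
class ChargeProfile:
    """Per-residue charges, windowed local charge density and NCPR."""

    protein_id: str
    state: PhosphoState
    charges: np.ndarray
    window_size: int
    density: np.ndarray  # enumerated C-terminus -> N-terminus, full windows only
    centers: np.ndarray  # 1-based window-center coordinates, same order
    ncpr: float
    too_short: bool = False  # sequence shorter than the window: empty density

    def as_density_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_id,
                "center_position": self.centers.astype(int),
                "density": self.density,
            }
        )


def _charge_vector(
    record: ProteinRecord, phospho_positions: frozenset[int]
) -> np.ndarray:
    charges = np.fromiter(
        (_CHARGE.get(aa, 0.0) for aa in record.sequence),
        dtype=float,
        count=len(record),
    )
    if phospho_positions:
        idx = np.fromiter(phospho_positions, dtype=int) - 1
        charges[idx] = -2.0
    return charges


def charge_profile(
    record: ProteinRecord,
    sites: Optional[PhosphoSiteSet] = None,
    state: PhosphoState = HYPO,
    window: int = DEFAULT_WINDOW,
) -> ChargeProfile:
    """Charge profile of one protein in one phosphorylation state.

    The density track holds the mean charge of every full ``window``-residue
    window, enumerated starting at the C-terminus and sliding toward the
    N-terminus; each value is reported at its 1-based center coordinate.
    Sequences shorter than the window get an empty density track (flagged),
    but NCPR is still valid.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    effective = state.effective_sites(record, sites)
    charges = _charge_vector(record, effective)
    L = len(charges)
    value = float(charges.sum() / L)
    if L < window:
        warnings.warn(
            f"{record.id}: length {L} < window {window}; density track empty",
            stacklevel=2,
        )
        return ChargeProfile(
            record.id,
            state,
            charges,
            window,
            np.empty(0),
            np.empty(0, dtype=int),
            value,
            too_short=True,
        )
    # means of all full windows in N->C order, then reversed to run C->N
    means = np.convolve(charges, np.ones(window), mode="valid") / window
    half = (window - 1) // 2
    centers_nc = np.arange(1, L - window + 2) + half  # 1-based centers, N->C
    return ChargeProfile(
        record.id,
        state,
        charges,
        window,
        means[::-1].copy(),
        centers_nc[::-1].copy(),
        value,
    )


def ncpr(
    record: ProteinRecord,
    sites: Optional[PhosphoSiteSet] = None,
    state: PhosphoState = HYPO,
) -> float:
    """Net charge per residue: summed residue charges divided by length."""
    effective = state.effective_sites(record, sites)
    charges = _charge_vector(record, effective)
    return float(charges.sum() / len(charges))


def phospho_variants(
    record: ProteinRecord,
    observed_sites: Optional[PhosphoSiteSet] = None,
    region: Optional[tuple[int, int]] = None,
    window: int = DEFAULT_WINDOW,
) -> dict[str, ChargeProfile]:
    """Hypo / observed / hyper charge profiles of the same sequence.

    Adding phosphates only lowers the charge sum, so the NCPR ordering
    hyper <= observed <= hypo always holds.
    """
    profiles = {
        kind: charge_profile(
            record, observed_sites, PhosphoState(kind, region), window=window
        )
        for kind in ("hypo", "observed", "hyper")
    }
    return profiles


@dataclass
class ProteomeChargeSummary:
    """Rank-ordered proteome NCPR table with +/-2 SD extreme groups."""

    table: pd.DataFrame  # columns: id, length, ncpr, rank, group
    mean_ncpr: float
    sd_ncpr: float
    low_threshold: float
    high_threshold: float
    min_length: int

    def groups(self) -> pd.Series:
        return self.table.set_index("id")["group"]

    def counts(self) -> dict[str, int]:
        c = self.table["group"].value_counts()
        return {g: int(c.get(g, 0)) for g in ("low", "mid", "high")}


def classify_ncpr(
    values: Sequence[float], low_threshold: float, high_threshold: float
) -> list[str]:
    """Strict-inequality grouping: low iff ncpr < low threshold, high iff
    ncpr > high threshold, mid otherwise (ties at a threshold are mid)."""
    out = []
    for v in values:
        if v < low_threshold:
            out.append("low")
        elif v > high_threshold:
            out.append("high")
        else:
            out.append("mid")
    return out


def proteome_charge_summary(
    records: Iterable[ProteinRecord],
    min_length: int = 1,
    state: PhosphoState = HYPO,
    sites: Optional[Mapping[str, PhosphoSiteSet]] = None,
) -> ProteomeChargeSummary:
    """Rank every protein by NCPR and split off the +/-2 SD extremes.

    The default state is unmodified (hypo): the proteome-wide ranking is a
    property of the bare sequences, before any PTM consideration. Thresholds
    use the sample (n-1) standard deviation. Ranks run 1..N in ascending NCPR
    (ties broken by accession for determinism), so the table is directly
    plottable as an S-graph.
    """
    rows = []
    for rec in records:
        if len(rec) < min_length:
            continue
        s = sites.get(rec.id) if sites else None
        rows.append((rec.id, len(rec), ncpr(rec, s, state)))
    if len(rows) < 2:
        raise ValueError(
            f"need >= 2 proteins after min_length={min_length} filter, got {len(rows)}"
        )
    df = pd.DataFrame(rows, columns=["id", "length", "ncpr"])
    mean = float(df["ncpr"].mean())
    sd = float(df["ncpr"].std(ddof=1))
    low = mean - 2.0 * sd
    high = mean + 2.0 * sd
    df = df.sort_values(["ncpr", "id"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["group"] = classify_ncpr(df["ncpr"], low, high)
    return ProteomeChargeSummary(df, mean, sd, low, high, min_length)
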