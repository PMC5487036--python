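"""Geometric detection of intramolecular isopeptide-bond triads.

CnaB-type domains lock their first and last β-strand together through an
amide bond between a lysine NZ and the side-chain carbon of an
asparagine or aspartate, formed autocatalytically with the help of a
nearby glutamate or aspartate that shuttles protons.  A deposited
structure shows this either as a formed (covalent) bond, with NZ-CG at
bonding distance, or as a reaction-competent (proximal) pose.

Detection is purely geometric: a reactive Lys is any Lys whose NZ lies
within ``proximal_max`` of an Asn/Asp CG; the nearest such acceptor is
paired with it, and the nearest carboxylate carbon of a Glu/Asp within
``catalytic_max`` of NZ is attached as the catalytic residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structure_io import ResidueRecord, StructureModel

__all__ = [
    "DetectionParams",
    "ActiveSiteTriad",
    "IsopeptideBond",
    "detect_isopeptide",
    "triad_in_ranges",
]

logger = logging.getLogger(__name__)

_ACCEPTOR_RESNAMES = ("ASN", "ASP")
_CATALYTIC_ATOM = {"GLU": "CD", "ASP": "CG"}


@dataclass(frozen=True)
class DetectionParams:
    """Distance thresholds, in Angstrom.

    ``covalent_max`` separates formed bonds (deposited covalent NZ-CG
    distances sit near 1.3-1.4 Å) from reaction-competent proximity;
    ``proximal_max`` bounds what counts as an active site at all;
    ``catalytic_max`` bounds the Lys-NZ to Glu/Asp carboxylate-carbon
    distance for the catalytic assignment.
    """

    covalent_max: float = 1.8
    proximal_max: float = 4.0
    catalytic_max: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 < self.covalent_max < self.proximal_max):
            raise ValueError("require 0 < covalent_max < proximal_max")
        if self.catalytic_max <= 0:
            raise ValueError("catalytic_max must be positive")


@dataclass(frozen=True)
class ActiveSiteTriad:
    lys: ResidueRecord
    acceptor: ResidueRecord
    catalytic: ResidueRecord | None = None

    def __post_init__(self) -> None:
        if self.lys.res_name != "LYS":
            raise ValueError(f"reactive residue must be LYS, got {self.lys.res_name}")
        if self.acceptor.res_name not in _ACCEPTOR_RESNAMES:
            raise ValueError(f"acceptor must be ASN or ASP, got {self.acceptor.res_name}")
        if self.catalytic is not None and self.catalytic.res_name not in _CATALYTIC_ATOM:
            raise ValueError(f"catalytic must be GLU or ASP, got {self.catalytic.res_name}")

    def __str__(self) -> str:
        cat = self.catalytic.label if self.catalytic else "-"
        return f"Lys {self.lys.chain_id}{self.lys.res_seq} / {self.acceptor.label} / {cat}"


@dataclass(frozen=True)
class IsopeptideBond:
    triad: ActiveSiteTriad
    nz_cg_distance: float  # Angstrom
    state: str  # "covalent" | "proximal"
    catalytic_distance: float | None = None

    def __post_init__(self) -> None:
        if self.state not in ("covalent", "proximal"):
            raise ValueError(f"unknown bond state {self.state!r}")


def detect_isopeptide(model: StructureModel,
                      params: DetectionParams = DetectionParams(),
                      chain: str | None = None) -> list[IsopeptideBond]:
    """Detect reactive Lys/Asn(Asp)/Glu(Asp) triads in a structure.

    Each Lys is reported at most once, paired with the nearest acceptor
    (ties broken by lower residue number); results are sorted by NZ-CG
    distance.  Lys residues lacking an NZ atom are skipped with a logged
    warning rather than raising, since truncated side chains are common
    in deposited structures.
    """
    residues = model.residues(chain)
    lysines = [r for r in residues if r.res_name == "LYS"]
    acceptors = [r for r in residues if r.res_name in _ACCEPTOR_RESNAMES and r.has_atom("CG")]
    catalytics = [
        r for r in residues
        if r.res_name in _CATALYTIC_ATOM and r.has_atom(_CATALYTIC_ATOM[r.res_name])
    ]

    bonds: list[IsopeptideBond] = []
    for lys in lysines:
        if not lys.has_atom("NZ"):
            logger.warning("skipping %s: no NZ atom", lys.label)
            continue
        nz = lys.atom("NZ").coords
        best: tuple[float, int, ResidueRecord] | None = None
        for acc in acceptors:
            if acc.key == lys.key:
                continue
            d = float(np.linalg.norm(nz - acc.atom("CG").coords))
            if d <= params.proximal_max:
                cand = (d, acc.res_seq, acc)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        if best is None:
            continue
        d_acc, _, acceptor = best

        cat_best: tuple[float, int, ResidueRecord] | None = None
        for cat in catalytics:
            if cat.key in (lys.key, acceptor.key):
                continue
            d = float(np.linalg.norm(nz - cat.atom(_CATALYTIC_ATOM[cat.res_name]).coords))
            if d <= params.catalytic_max:
                cand = (d, cat.res_seq, cat)
                if cat_best is None or cand[:2] < cat_best[:2]:
                    cat_best = cand

        state = "covalent" if d_acc <= params.covalent_max else "proximal"
        bonds.append(
            IsopeptideBond(
                triad=ActiveSiteTriad(
                    lys=lys,
                    acceptor=acceptor,
                    catalytic=cat_best[2] if cat_best else None,
                ),
                nz_cg_distance=d_acc,
                state=state,
                catalytic_distance=cat_best[0] if cat_best else None,
            )
        )
    bonds.sort(key=lambda b: b.nz_cg_distance)
    return bonds


def triad_in_ranges(triad: ActiveSiteTriad, split) -> dict[str, str]:
    """Report where each triad member falls relative to a split.

    ``split`` is a :class:`~cnascreen.split_design.SplitSpec`.  Each of
    ``lys``, ``acceptor`` and (if present) ``catalytic`` is mapped to one
    of ``"catcher"``, ``"tag"``, ``"deleted"`` or ``"outside"``.
    """
    def place(res: ResidueRecord) -> str:
        n = res.res_seq
        if split.catcher_first <= n <= split.catcher_last:
            return "catcher"
        if split.tag_first <= n <= split.tag_last:
            return "tag"
        if split.catcher_last < n < split.tag_first:
            return "deleted"
        return "outside"

    report = {"lys": place(triad.lys), "acceptor": place(triad.acceptor)}
    if triad.catalytic is not None:
        report["catalytic"] = place(triad.catalytic)
    return report
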