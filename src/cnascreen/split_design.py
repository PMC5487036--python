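"""Turn a parent CnaB domain into validated tag/catcher constructs.

A split specification names two author-numbered residue ranges on the
parent chain: the catcher (the large folded moiety, which keeps the
reactive lysine and the catalytic Glu/Asp) and the tag (the short
C-terminal peptide carrying the acceptor Asn/Asp).  Residues between the
two ranges are the deleted region; they are derived from the spec, never
supplied by the user, so the bookkeeping identity

    |catcher| + |deleted| + |tag| = |parent range|

holds by construction.  The module also builds capped structures for
simulation input, applies tag/catcher length and sequence variants,
generates active-site point mutants, assembles expression fusion
constructs (His6 leader, HA tag, GS linkers, MBP, mCherry) with their
average masses, and emits a machine-readable MD preparation recipe.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .isopeptide_detect import ActiveSiteTriad, triad_in_ranges
from .seq_screen import compute_mass
from .structure_io import (
    AtomRecord,
    ResidueRecord,
    StructureModel,
    residue_sequence,
    select_residues,
)

__all__ = [
    "SplitSpec",
    "ConstructSet",
    "VariantSpec",
    "FusionPartLibrary",
    "FusionReport",
    "PrepProtocol",
    "SplitValidationError",
    "TABLE_SPLITS",
    "KNOWN_TRIADS",
    "make_split",
    "cap_termini",
    "apply_variant",
    "make_point_mutant",
    "assemble_fusion",
    "emit_md_recipe",
    "read_md_recipe",
]


class SplitValidationError(ValueError):
    """A split places an active-site residue in the wrong moiety."""


@dataclass(frozen=True)
class SplitSpec:
    """Catcher/tag residue ranges (author numbering, inclusive)."""

    chain: str
    catcher_first: int
    catcher_last: int
    tag_first: int
    tag_last: int

    def __post_init__(self) -> None:
        ok = self.catcher_first <= self.catcher_last < self.tag_first <= self.tag_last
        if not ok:
            raise ValueError(
                "require catcher_first <= catcher_last < tag_first <= tag_last, "
                f"got {self.catcher_first}-{self.catcher_last}/{self.tag_first}-{self.tag_last}"
            )

    @property
    def deleted_range(self) -> range:
        """Author numbers removed by the split (possibly empty)."""
        return range(self.catcher_last + 1, self.tag_first)

    @property
    def domain_range(self) -> tuple[int, int]:
        """The parent domain span: first catcher to last tag residue."""
        return (self.catcher_first, self.tag_last)


# Split boundaries of the four candidate systems (author numbering of the
# deposited parent structures), and the core regions used elsewhere.
TABLE_SPLITS: dict[str, SplitSpec] = {
    "3phs": SplitSpec("A", 152, 245, 248, 263),
    "4oq1": SplitSpec("A", 146, 240, 246, 259),
    "3kptN": SplitSpec("A", 164, 255, 258, 272),
    "3kptC": SplitSpec("A", 409, 500, 505, 518),
}

# Active-site triads known for the two systems whose mutants were
# characterized: (reactive Lys, acceptor Asn, catalytic Glu).
KNOWN_TRIADS: dict[str, tuple[int, int, int]] = {
    "4oq1": (155, 252, 222),
    "3kptC": (417, 512, 472),
}


@dataclass
class ConstructSet:
    catcher: StructureModel
    tag: StructureModel
    deleted: list[ResidueRecord]
    catcher_seq: str
    tag_seq: str
    spec: SplitSpec
    parent_label: str = ""
    caps: dict[str, str] = field(default_factory=dict)

    def combined(self) -> StructureModel:
        """Catcher + tag as one two-chain model (for writing/simulation)."""
        out = StructureModel(header_id=self.parent_label or "construct")
        for m in (self.catcher, self.tag):
            for cid, residues in m.chains.items():
                out.chains[cid] = [r for r in residues]
        return out

    @property
    def deleted_numbers(self) -> list[int]:
        return [r.res_seq for r in self.deleted]


def _rechain(model: StructureModel, new_id: str) -> StructureModel:
    out = StructureModel(header_id=model.header_id)
    residues = model.residues()
    out.chains[new_id] = [
        ResidueRecord(new_id, r.res_seq, r.res_name,
                      [AtomRecord(a.serial, a.name, a.element, a.coords.copy(),
                                  a.alt_loc, a.occupancy, a.b_factor, a.is_hetatm)
                       for a in r.atoms],
                      r.i_code)
        for r in residues
    ]
    return out


def make_split(parent: StructureModel, spec: SplitSpec,
               triad: ActiveSiteTriad) -> ConstructSet:
    """Split a parent domain into a validated catcher/tag construct pair.

    The catcher becomes chain ``C`` and the tag chain ``T`` (author
    residue numbers are kept).  Validation enforces the Spy-like
    topology: reactive Lys and the catalytic residue must fall in the
    catcher range, the acceptor in the tag range, and no triad member in
    the deleted region.
    """
    placement = triad_in_ranges(triad, spec)
    problems = []
    for member, want in (("lys", "catcher"), ("acceptor", "tag"), ("catalytic", "catcher")):
        got = placement.get(member)
        if got is None:
            continue
        res = getattr(triad, member)
        if got == "deleted":
            problems.append(f"{member} ({res.label}) falls in the deleted region "
                            f"{spec.deleted_range.start}-{spec.deleted_range.stop - 1}")
        elif got != want:
            problems.append(f"{member} ({res.label}) expected in {want} range, found in {got}")
    if problems:
        msg = "; ".join(problems)
        if placement.get("lys") == "tag" and placement.get("acceptor") == "catcher":
            msg += (" — this looks like an N-terminal-tag (Snoop-like) topology, "
                    "which this toolkit does not support")
        raise SplitValidationError(msg)

    catcher = _rechain(select_residues(parent, spec.chain, spec.catcher_first,
                                       spec.catcher_last), "C")
    tag = _rechain(select_residues(parent, spec.chain, spec.tag_first,
                                   spec.tag_last), "T")
    if len(spec.deleted_range) > 0:
        deleted = select_residues(parent, spec.chain, spec.deleted_range.start,
                                  spec.deleted_range.stop - 1).residues()
    else:
        deleted = []

    # Warn (not fail) on numbering gaps inside the requested ranges.
    import logging
    logger = logging.getLogger(__name__)
    for name, model_, lo, hi in (("catcher", catcher, spec.catcher_first, spec.catcher_last),
                                 ("tag", tag, spec.tag_first, spec.tag_last)):
        present = {r.res_seq for r in model_.residues()}
        gaps = sorted(set(range(lo, hi + 1)) - present)
        if gaps:
            logger.warning("%s range %d-%d has numbering gaps: %s", name, lo, hi, gaps)

    return ConstructSet(
        catcher=catcher,
        tag=tag,
        deleted=deleted,
        catcher_seq=residue_sequence(catcher),
        tag_seq=residue_sequence(tag),
        spec=spec,
        parent_label=parent.header_id,
    )


# ---------------------------------------------------------------------------
# terminal capping

_CAP_SCHEMES = ("acetyl", "n_methyl", "ionic")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("degenerate geometry while placing cap atoms")
    return v / n


def _perpendicular(d: np.ndarray, r: np.ndarray) -> np.ndarray:
    w = r - np.dot(r, d) * d
    if np.linalg.norm(w) < 1e-6:  # r parallel to d: fall back to a fixed axis
        probe = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(probe, d)) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        w = probe - np.dot(probe, d) * d
    return _unit(w)


def cap_termini(model: StructureModel, n_term: str = "ionic",
                c_term: str = "ionic", chain: str | None = None) -> StructureModel:
    """Cap chain termini with ACE / NME residues, or leave them ionic.

    ``acetyl`` prepends an ACE residue before the N-terminus; ``n_methyl``
    appends an NME residue after the C-terminus.  Cap heavy atoms are
    placed deterministically by extending the terminal peptide-bond
    geometry with ideal bond lengths (C-N 1.33 Å, C=O 1.23 Å, C-CH3
    1.50 Å).  ``ionic`` leaves a terminus unmodified (newly created split
    termini stay charged).
    """
    if n_term not in ("acetyl", "ionic"):
        raise ValueError(f"n_term must be 'acetyl' or 'ionic', got {n_term!r}")
    if c_term not in ("n_methyl", "ionic"):
        raise ValueError(f"c_term must be 'n_methyl' or 'ionic', got {c_term!r}")

    out = model.copy()
    chain_ids = [chain] if chain is not None else list(out.chains)
    for cid in chain_ids:
        residues = out.chains[cid]
        if n_term == "acetyl":
            first = residues[0]
            for need in ("N", "CA", "C"):
                if not first.has_atom(need):
                    raise ValueError(f"cannot cap N-terminus of {first.label}: missing {need}")
            n = first.atom("N").coords
            ca = first.atom("CA").coords
            c = first.atom("C").coords
            d = _unit(n - ca)
            c_ace = n + 1.33 * d
            w = _perpendicular(d, c - ca)
            ace = ResidueRecord(cid, first.res_seq - 1, "ACE", [
                AtomRecord(0, "CH3", "C", c_ace + 1.50 * d),
                AtomRecord(0, "C", "C", c_ace),
                AtomRecord(0, "O", "O", c_ace + 1.23 * w),
            ])
            residues.insert(0, ace)
        if c_term == "n_methyl":
            last = residues[-1]
            for need in ("CA", "C"):
                if not last.has_atom(need):
                    raise ValueError(f"cannot cap C-terminus of {last.label}: missing {need}")
            ca = last.atom("CA").coords
            c = last.atom("C").coords
            d = _unit(c - ca)
            n_nme = c + 1.33 * d
            nme = ResidueRecord(cid, last.res_seq + 1, "NME", [
                AtomRecord(0, "N", "N", n_nme),
                AtomRecord(0, "CH3", "C", n_nme + 1.46 * d),
            ])
            residues.append(nme)
    return out


# ---------------------------------------------------------------------------
# sequence variants and mutants


@dataclass(frozen=True)
class VariantSpec:
    """A tag/catcher length or sequence variant.

    ``n_extension`` is either a literal sequence prepended to the
    construct or an author-numbered ``(first, last)`` range taken from
    the parent.  At most one C-terminal edit (truncation or replacement)
    is allowed per variant.
    """

    name: str = ""
    n_extension: str | tuple[int, int] | None = None
    c_truncation: int = 0
    c_replacement: str | None = None

    def __post_init__(self) -> None:
        if self.c_truncation < 0:
            raise ValueError("c_truncation must be >= 0")
        if self.c_truncation and self.c_replacement is not None:
            raise ValueError("at most one C-terminal edit per variant")


def apply_variant(construct_seq: str, parent: StructureModel | None,
                  v: VariantSpec, chain: str | None = None) -> str:
    """Apply a variant to a construct sequence.

    The length change equals |extension| - |truncation| (replacements are
    same-length by construction here only if the replacement has the same
    length as the stretch it overwrites).
    """
    seq = construct_seq
    if v.c_truncation:
        if v.c_truncation > len(seq):
            raise ValueError(
                f"cannot truncate {v.c_truncation} residues from a {len(seq)}-residue sequence")
        seq = seq[: len(seq) - v.c_truncation]
    elif v.c_replacement is not None:
        if len(v.c_replacement) > len(seq):
            raise ValueError("replacement longer than the sequence")
        seq = seq[: len(seq) - len(v.c_replacement)] + v.c_replacement.upper()
    if v.n_extension is not None:
        if isinstance(v.n_extension, str):
            ext = v.n_extension.upper()
        else:
            if parent is None:
                raise ValueError("numbered extension requires the parent structure")
            first, last = v.n_extension
            ext = residue_sequence(parent, chain, first, last)
        seq = ext + seq
    return seq


_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def make_point_mutant(seq: str, mutation: str, numbering_offset: int) -> str:
    """Apply a single substitution given in author numbering.

    ``numbering_offset`` is the author number of the first residue of
    ``seq``; mutation strings look like ``"K155A"``.  The stated
    wild-type letter is checked against the sequence.
    """
    m = _MUTATION_RE.match(mutation.strip())
    if not m:
        raise ValueError(f"cannot parse mutation {mutation!r}")
    wt, num, new = m.group(1), int(m.group(2)), m.group(3)
    idx = num - numbering_offset
    if not 0 <= idx < len(seq):
        raise ValueError(f"position {num} outside the sequence "
                         f"({numbering_offset}-{numbering_offset + len(seq) - 1})")
    if seq[idx] != wt:
        raise ValueError(f"wild-type mismatch at {num}: expected {wt}, found {seq[idx]}")
    return seq[:idx] + new + seq[idx + 1:]


# ---------------------------------------------------------------------------
# fusion assembly


class FusionPartLibrary:
    """Named sequence parts used to assemble expression constructs.

    The default library ships His6 leader, HA tag, the two glycine-serine
    linkers, mature MBP and mCherry as an editable FASTA data file;
    construct masses therefore depend on that file, and fusion reports
    echo a short checksum per part.
    """

    def __init__(self, parts: dict[str, str] | None = None):
        self._parts: dict[str, str] = {}
        for name, seq in (parts or {}).items():
            self.add(name, seq)

    @classmethod
    def default(cls) -> "FusionPartLibrary":
        lib = cls()
        text = resources.files("cnascreen").joinpath("data/fusion_parts.fasta").read_text()
        name, chunks = None, []
        for line in text.splitlines():
            if line.startswith(">"):
                if name is not None:
                    lib.add(name, "".join(chunks))
                name, chunks = line[1:].split()[0], []
            elif line.strip():
                chunks.append(line.strip())
        if name is not None:
            lib.add(name, "".join(chunks))
        return lib

    def add(self, name: str, seq: str) -> None:
        seq = seq.strip().upper()
        if not seq:
            raise ValueError(f"part {name!r} has an empty sequence")
        self._parts[name] = seq

    def __contains__(self, name: str) -> bool:
        return name in self._parts

    def __getitem__(self, name: str) -> str:
        if name not in self._parts:
            raise KeyError(f"unknown fusion part {name!r}; known: {sorted(self._parts)}")
        return self._parts[name]

    def names(self) -> list[str]:
        return list(self._parts)

    def checksum(self, name: str) -> str:
        return hashlib.sha1(self[name].encode()).hexdigest()[:8]


@dataclass
class FusionReport:
    sequence: str
    spans: list[tuple[str, int, int]]  # (part, start, end) 0-based half-open
    mass_da: float
    checksums: dict[str, str]

    @property
    def mass_kda(self) -> float:
        return self.mass_da / 1000.0


def assemble_fusion(parts: list[str], library: FusionPartLibrary) -> FusionReport:
    """Concatenate named parts in order and report spans and total mass."""
    if not parts:
        raise ValueError("no parts to assemble")
    seq_chunks: list[str] = []
    spans: list[tuple[str, int, int]] = []
    pos = 0
    for name in parts:
        part_seq = library[name]
        spans.append((name, pos, pos + len(part_seq)))
        seq_chunks.append(part_seq)
        pos += len(part_seq)
    sequence = "".join(seq_chunks)
    return FusionReport(
        sequence=sequence,
        spans=spans,
        mass_da=compute_mass(sequence),
        checksums={name: library.checksum(name) for name in dict.fromkeys(parts)},
    )


# ---------------------------------------------------------------------------
# MD preparation recipe


@dataclass(frozen=True)
class PrepProtocol:
    """Constants of the simulation preparation protocol.

    Restraint stages are (force constant kcal/mol/A^2, selection,
    duration ns); heating target and production length follow the
    standard explicit-solvent NPT setup used for these systems.
    """

    solvent_margin: float = 10.0  # Angstrom
    water_model: str = "TIP3P"
    box: str = "truncated_octahedron"
    neutralize: bool = True
    temperature: float = 310.0  # K
    restraint_stages: tuple[tuple[float, str, float], ...] = (
        (5.0, "all-protein", 0.1),
        (5.0, "backbone-CA", 0.4),
        (0.0, "none", 0.5),
    )
    production_ns: float = 200.0
    timestep_fs: float = 2.0
    constraints: str = "SHAKE (bonds involving hydrogen)"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if any(dur <= 0 for _, _, dur in self.restraint_stages):
            raise ValueError("stage durations must be positive")


def emit_md_recipe(constructs: ConstructSet | StructureModel,
                   protocol: PrepProtocol = PrepProtocol(),
                   isopeptide_bond_present: bool | None = None) -> str:
    """Emit a YAML preparation recipe for a construct set or intact domain.

    Split (tag/catcher) systems are prepared without the isopeptide bond,
    mimicking the initial recognition stage; intact domains keep it.  The
    flag can be forced explicitly.
    """
    if isinstance(constructs, ConstructSet):
        is_split = True
        chains = {
            "C": {"role": "catcher", "n_residues": len(constructs.catcher.residues()),
                  "termini": {"N": constructs.caps.get("catcher_N", "acetyl" if
                              constructs.spec.catcher_first == constructs.spec.domain_range[0]
                              else "ionic"),
                              "C": "ionic"}},
            "T": {"role": "tag", "n_residues": len(constructs.tag.residues()),
                  "termini": {"N": "ionic",
                              "C": "n_methyl" if constructs.spec.tag_last ==
                              constructs.spec.domain_range[1] else "ionic"}},
        }
        label = constructs.parent_label or "construct"
    else:
        is_split = False
        chains = {
            cid: {"role": "domain", "n_residues": len(res),
                  "termini": {"N": "acetyl", "C": "n_methyl"}}
            for cid, res in constructs.chains.items()
        }
        label = constructs.header_id or "domain"
    if isopeptide_bond_present is None:
        isopeptide_bond_present = not is_split

    doc = {
        "system": label,
        "kind": "tag_catcher" if is_split else "intact_domain",
        "isopeptide_bond_present": bool(isopeptide_bond_present),
        "chains": chains,
        "solvation": {
            "water_model": protocol.water_model,
            "box": protocol.box,
            "margin_angstrom": protocol.solvent_margin,
            "neutralize_with_monovalent_ions": protocol.neutralize,
        },
        "minimization": "three-step with decreasing harmonic restraints",
        "heating": {
            "target_temperature_K": protocol.temperature,
            "stages": [
                {"restraint_kcal_mol_A2": k, "selection": sel, "duration_ns": dur}
                for k, sel, dur in protocol.restraint_stages
            ],
        },
        "production": {
            "ensemble": "NPT",
            "length_ns": protocol.production_ns,
            "timestep_fs": protocol.timestep_fs,
            "constraints": protocol.constraints,
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)


def read_md_recipe(text: str) -> dict:
    """Parse a recipe produced by :func:`emit_md_recipe`."""
    doc = yaml.safe_load(text)
    for key in ("system", "kind", "isopeptide_bond_present", "heating", "production"):
        if key not in doc:
            raise ValueError(f"recipe is missing key {key!r}")
    return doc
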