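"""End-to-end screening of candidate domains for tag/catcher design.

For each configured system the pipeline detects the reactive triad,
validates the split, builds the constructs, and — when trajectories for
the intact domain and the split system are supplied — computes the three
comparative stability metrics and renders a verdict:

* ``dissociated``  — the tag leaves the catcher (contact fraction below
  ``contact_min``); takes precedence over everything else;
* ``destabilized`` — the split system's core RMSD rises by more than
  ``delta_rmsd_max`` over the intact domain, or it retains less than
  ``lj_fraction`` of the domain's tag-catcher van-der-Waals energy;
* ``comparable``   — neither of the above; the split behaves like its
  parent, the outcome that qualifies a system for experimental testing.

The numeric thresholds are explicit stand-ins for a qualitative
"similar RMSD / no dissociation" judgement and are echoed in every
report; changing them never alters metric values, only verdicts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .isopeptide_detect import DetectionParams, detect_isopeptide
from .split_design import ConstructSet, SplitSpec, make_split
from .structure_io import StructureModel, Trajectory
from .traj_metrics import (
    CoreRegion,
    LJParamTable,
    MetricSeries,
    contact_fraction,
    core_rmsd_series,
    find_sheet_hbond_pairs,
    group_indices,
    hbond_distance_series,
    infer_exclusions,
    lj_energy_series,
)

__all__ = [
    "VerdictThresholds",
    "SystemConfig",
    "SystemMetrics",
    "SystemResult",
    "ScreenReport",
    "run_screen",
    "compare_domain_vs_split",
    "render_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VerdictThresholds:
    contact_min: float = 0.95      # fraction of frames in contact
    delta_rmsd_max: float = 1.0    # A, split minus domain mean core RMSD
    lj_fraction: float = 0.5       # fraction of domain vdW energy retained
    contact_cutoff: float = 4.5    # A, heavy-atom contact distance
    hbond_d_max: float = 3.5       # A, reference N...O cutoff

    def describe(self) -> str:
        return (f"contact_min={self.contact_min}, delta_rmsd_max={self.delta_rmsd_max} A, "
                f"lj_fraction={self.lj_fraction}, contact_cutoff={self.contact_cutoff} A")


@dataclass
class SystemConfig:
    label: str
    parent: StructureModel
    split: SplitSpec
    core: CoreRegion
    domain_traj: Trajectory | None = None
    split_traj: Trajectory | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    thresholds: VerdictThresholds = field(default_factory=VerdictThresholds)
    lj_params: LJParamTable = field(default_factory=LJParamTable)


@dataclass
class SystemMetrics:
    core_rmsd: MetricSeries
    lj: MetricSeries
    hbond_means: dict[str, float]
    contact_fraction: float | None = None


@dataclass
class SystemResult:
    label: str
    triads: list = field(default_factory=list)
    constructs: ConstructSet | None = None
    domain_metrics: SystemMetrics | None = None
    split_metrics: SystemMetrics | None = None
    verdict: str | None = None
    error: str | None = None


@dataclass
class ScreenReport:
    results: list[SystemResult]
    thresholds: VerdictThresholds
    lj_table_name: str = "builtin-element-lj"

    @property
    def any_errors(self) -> bool:
        return any(r.error for r in self.results)


def compare_domain_vs_split(domain: SystemMetrics, split: SystemMetrics,
                            thresholds: VerdictThresholds = VerdictThresholds()) -> str:
    """Render the verdict; precedence dissociated > destabilized > comparable."""
    for name, m in (("domain", domain), ("split", split)):
        if m is None or m.core_rmsd is None or m.lj is None:
            raise ValueError(f"missing {name} metrics")
    if split.contact_fraction is None:
        raise ValueError("missing split contact_fraction")
    if split.contact_fraction < thresholds.contact_min:
        return "dissociated"
    if split.core_rmsd.mean - domain.core_rmsd.mean > thresholds.delta_rmsd_max:
        return "destabilized"
    # vdW energies are negative: retaining less than lj_fraction of the
    # domain's (more negative) binding energy flags destabilization
    if split.lj.mean > thresholds.lj_fraction * domain.lj.mean:
        return "destabilized"
    return "comparable"


def _metrics_for(traj: Trajectory, config: SystemConfig, is_split: bool) -> SystemMetrics:
    spec = config.split
    top = traj.topology
    if is_split:
        tag_sel = ("T", spec.tag_first, spec.tag_last)
        catcher_sel = ("C", spec.catcher_first, spec.catcher_last)
    else:
        tag_sel = (spec.chain, spec.tag_first, spec.tag_last)
        catcher_sel = (spec.chain, spec.catcher_first, spec.catcher_last)
    tag_idx = group_indices(top, *tag_sel)
    catcher_idx = group_indices(top, *catcher_sel)
    if not tag_idx or not catcher_idx:
        raise ValueError(f"empty tag or catcher selection for {config.label}")
    exclusions = None if is_split else infer_exclusions(top, tag_idx, catcher_idx)
    lj = lj_energy_series(traj, tag_idx, catcher_idx, config.lj_params, exclusions)
    rmsd = core_rmsd_series(traj, config.core)
    pairs = find_sheet_hbond_pairs(top, tag_sel, catcher_sel,
                                   d_max=config.thresholds.hbond_d_max)
    hb = hbond_distance_series(traj, pairs)
    cf = contact_fraction(traj, tag_idx, catcher_idx, config.thresholds.contact_cutoff)
    return SystemMetrics(
        core_rmsd=rmsd,
        lj=lj,
        hbond_means={k: s.mean for k, s in hb.items()},
        contact_fraction=cf,
    )


def run_screen(configs: list[SystemConfig]) -> ScreenReport:
    """Run the full screening pipeline over a list of systems.

    Sequence/structure stages (triad detection, split validation,
    construct bookkeeping) always run; the trajectory metrics and the
    verdict are added when both trajectories are present.  A failure in
    one system is recorded on its result and does not abort the others.
    """
    results: list[SystemResult] = []
    thresholds = configs[0].thresholds if configs else VerdictThresholds()
    lj_name = configs[0].lj_params.name if configs else LJParamTable().name
    for cfg in configs:
        res = SystemResult(label=cfg.label)
        try:
            bonds = detect_isopeptide(cfg.parent, cfg.detection, chain=cfg.split.chain)
            res.triads = bonds
            if not bonds:
                raise ValueError("no isopeptide triad detected in the parent domain")
            res.constructs = make_split(cfg.parent, cfg.split, bonds[0].triad)
            if cfg.domain_traj is not None and cfg.split_traj is not None:
                res.domain_metrics = _metrics_for(cfg.domain_traj, cfg, is_split=False)
                res.split_metrics = _metrics_for(cfg.split_traj, cfg, is_split=True)
                res.verdict = compare_domain_vs_split(res.domain_metrics,
                                                      res.split_metrics, cfg.thresholds)
        except Exception as exc:  # per-system isolation
            logger.error("[%s] %s", cfg.label, exc)
            res.error = str(exc)
        results.append(res)
    return ScreenReport(results=results, thresholds=thresholds, lj_table_name=lj_name)


_COLUMNS = [
    "system", "triad", "bond_state", "nz_cg_A", "catcher_range", "tag_range",
    "deleted", "rmsd_domain_A", "rmsd_split_A", "lj_domain_kcal", "lj_split_kcal",
    "contact_fraction", "verdict", "error",
]


def _result_row(res: SystemResult) -> list[str]:
    def fmt(x, nd=2):
        return "" if x is None else f"{x:.{nd}f}"

    triad = bond_state = nz = ""
    if res.triads:
        b = res.triads[0]
        triad = str(b.triad)
        bond_state = b.state
        nz = f"{b.nz_cg_distance:.2f}"
    cr = tr = dr = ""
    if res.constructs is not None:
        s = res.constructs.spec
        cr = f"{s.catcher_first}-{s.catcher_last}"
        tr = f"{s.tag_first}-{s.tag_last}"
        dn = res.constructs.deleted_numbers
        dr = f"{dn[0]}-{dn[-1]}" if dn else "none"
    dm, sm = res.domain_metrics, res.split_metrics
    return [
        res.label, triad, bond_state, nz, cr, tr, dr,
        fmt(dm.core_rmsd.mean) if dm else "",
        fmt(sm.core_rmsd.mean) if sm else "",
        fmt(dm.lj.mean, 1) if dm else "",
        fmt(sm.lj.mean, 1) if sm else "",
        fmt(sm.contact_fraction) if sm and sm.contact_fraction is not None else "",
        res.verdict or "",
        res.error or "",
    ]


def render_report(report: ScreenReport, fmt: str = "tsv") -> str:
    """Render a screen report as TSV or Markdown (deterministic output)."""
    rows = [_result_row(r) for r in report.results]
    footer = (f"thresholds: {report.thresholds.describe()}; "
              f"LJ table: {report.lj_table_name}")
    if fmt == "tsv":
        lines = ["\t".join(_COLUMNS)]
        lines += ["\t".join(row) for row in rows]
        lines.append(f"# {footer}")
        return "\n".join(lines) + "\n"
    if fmt == "markdown":
        lines = ["| " + " | ".join(_COLUMNS) + " |",
                 "|" + "---|" * len(_COLUMNS)]
        lines += ["| " + " | ".join(row) + " |" for row in rows]
        lines.append("")
        lines.append(f"_{footer}_")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")
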