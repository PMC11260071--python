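"""In silico chimera and deletion design with collinear product prediction.

Chimeric trans-AT PKSs are assembled by cutting an acceptor protein at an
FSD-boundary fusion site (LPTYPFxxxxxW; NAHVILEE only as a negative
control), splicing in exchange units from donor proteins, and appending a
terminal segment.  Deletions remove a contiguous run of exchange units and
rejoin the flanks.  Substrate compatibility between the upstream module's
output chemistry and the downstream KS's native substrate is annotated —
never enforced, since mismatched chimeras remain productive, only at
reduced titers.

Product formulas follow the collinearity principle: each module applies an
integer element-count delta to the growing chain —

=============  =======================================
extension      +C2H2O   (decarboxylative malonyl condensation)
KR             +H2      (β-keto → β-hydroxy)
DH             −H2O     (β-hydroxy → enoyl)
halogenation   +Cl −H
offload        free acid +H2O; lactone ±0
=============  =======================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .architecture import (
    LPTYPF_X5_W,
    NAHVILEE,
    ExchangeUnit,
    MotifPattern,
    PKSProtein,
    find_motifs,
)
from .masscalc import formula_to_string

__all__ = [
    "SubstrateState",
    "SubstrateTag",
    "FusionSite",
    "ChimeraPlan",
    "DeletionPlan",
    "MODULE_DELTAS",
    "OFFLOAD_DELTAS",
    "PredictedProduct",
    "plan_chimera",
    "build_sequence",
    "check_substrate_match",
    "predict_product_formula",
]


class SubstrateState(str, Enum):
    beta_keto = "beta_keto"
    beta_hydroxy = "beta_hydroxy"
    enoyl = "enoyl"
    reduced = "reduced"
    unknown = "unknown"


@dataclass(frozen=True)
class SubstrateTag:
    """User-supplied chemistry of a module output / KS native substrate."""

    state: SubstrateState = SubstrateState.unknown
    alpha_delta_signature: str = ""


@dataclass(frozen=True)
class FusionSite:
    """A residue index in a protein coinciding with a motif boundary."""

    protein_id: str
    residue_index: int
    motif: str = "LPTYPFx5W"  # or "NAHVILEE"


@dataclass
class ChimeraPlan:
    """Acceptor prefix + ordered donor exchange units + terminal segment."""

    acceptor: PKSProtein
    prefix_end: int
    inserts: list[tuple[PKSProtein, ExchangeUnit]]
    terminal: tuple[PKSProtein, tuple[int, int]] | None
    site_motif: str = "LPTYPFx5W"
    control: bool = False

    def total_length(self) -> int:
        n = self.prefix_end + sum(len(u) for _, u in self.inserts)
        if self.terminal is not None:
            _, (s, e) = self.terminal
            n += e - s
        return n

    def junctions(self) -> list[int]:
        """Residue indices (in the chimera) where segments meet."""
        js = [self.prefix_end]
        pos = self.prefix_end
        for _, u in self.inserts:
            pos += len(u)
            js.append(pos)
        if self.terminal is None:
            js.pop()
        return js


@dataclass
class DeletionPlan:
    """Remove a contiguous run of exchange units from one protein."""

    target: PKSProtein
    units: list[ExchangeUnit]
    removed: list[int]  # indices into units, contiguous

    def __post_init__(self):
        if not self.removed:
            return
        r = sorted(self.removed)
        if r != list(range(r[0], r[-1] + 1)):
            raise ValueError("removed units must be contiguous")
        self.removed = r

    def junction(self) -> tuple[FusionSite, FusionSite]:
        lo = self.units[self.removed[0]].start
        hi = self.units[self.removed[-1]].end
        return (
            FusionSite(self.target.id, lo),
            FusionSite(self.target.id, hi),
        )


def _motif_for(name: str) -> MotifPattern:
    if name == "LPTYPFx5W":
        return LPTYPF_X5_W
    if name == "NAHVILEE":
        return NAHVILEE
    raise ValueError(f"unknown fusion motif {name!r}")


def _is_motif_boundary(protein: PKSProtein, index: int, motif: str, max_mismatch: int = 0) -> bool:
    """True if ``index`` is a terminus or lies immediately after a motif hit."""
    if index in (0, len(protein.sequence)):
        return True
    pattern = MotifPattern(_motif_for(motif).elements, max_mismatch)
    return any(h.end == index for h in find_motifs(protein.sequence, pattern))


def plan_chimera(
    acceptor: PKSProtein,
    site: FusionSite,
    inserts: list[tuple[PKSProtein, ExchangeUnit]],
    terminal: tuple[PKSProtein, tuple[int, int]] | None = None,
    force: bool = False,
) -> ChimeraPlan:
    """Validate and assemble a chimera plan.

    The acceptor is cut at ``site`` (which must coincide with a motif
    boundary of the site's motif type); donor units must themselves be
    motif-anchored in their source proteins unless ``force`` is given.
    Zero inserts yield a truncation(+terminal) plan.  NAHVILEE-site plans
    are flagged ``control=True``.
    """
    if site.protein_id != acceptor.id:
        raise ValueError("fusion site does not reference the acceptor protein")
    if not 0 <= site.residue_index <= len(acceptor.sequence):
        raise ValueError("fusion site outside acceptor sequence")
    if not _is_motif_boundary(acceptor, site.residue_index, site.motif):
        raise ValueError(
            f"{site.motif} motif boundary absent at residue {site.residue_index} "
            f"of {acceptor.id}"
        )
    for donor, unit in inserts:
        ok = _is_motif_boundary(donor, unit.start, "LPTYPFx5W") and _is_motif_boundary(
            donor, unit.end, "LPTYPFx5W"
        )
        if not ok and not force:
            raise ValueError(
                f"insert [{unit.start},{unit.end}) of {donor.id} is not "
                f"motif-anchored (pass force=True to override)"
            )
    return ChimeraPlan(
        acceptor=acceptor,
        prefix_end=site.residue_index,
        inserts=list(inserts),
        terminal=terminal,
        site_motif=site.motif,
        control=(site.motif == "NAHVILEE"),
    )


def build_sequence(plan: ChimeraPlan | DeletionPlan, context: int = 10):
    """Concatenate a plan into a protein string plus a junction report.

    The report lists, for each junction, the ``context``-residue windows on
    either side in the built sequence.
    """
    if isinstance(plan, DeletionPlan):
        seq = plan.target.sequence
        if not plan.removed:
            built = seq
            junctions: list[int] = []
        else:
            lo = plan.units[plan.removed[0]].start
            hi = plan.units[plan.removed[-1]].end
            built = seq[:lo] + seq[hi:]
            junctions = [lo]
    else:
        parts = [plan.acceptor.sequence[: plan.prefix_end]]
        for donor, unit in plan.inserts:
            parts.append(donor.sequence[unit.start : unit.end])
        if plan.terminal is not None:
            donor, (s, e) = plan.terminal
            parts.append(donor.sequence[s:e])
        built = "".join(parts)
        junctions = plan.junctions()
    report = [
        {
            "junction": j,
            "left": built[max(0, j - context) : j],
            "right": built[j : j + context],
        }
        for j in junctions
    ]
    return built, report


def check_substrate_match(upstream_out: SubstrateTag, downstream_in: SubstrateTag) -> str:
    """Annotate α-δ substrate compatibility: 'match' | 'mismatch' | 'unknown'.

    A mismatch never blocks a design — mismatched chimeras remain
    productive, typically at 3–50-fold reduced titers — it only annotates
    the design report.
    """
    if SubstrateState.unknown in (upstream_out.state, downstream_in.state):
        return "unknown"
    return "match" if upstream_out.state == downstream_in.state else "mismatch"


#: Per-module element-count deltas (configurable; extend for β-branching etc.).
MODULE_DELTAS: dict[str, dict[str, int]] = {
    "extension": {"C": 2, "H": 2, "O": 1},
    "KR": {"H": 2},
    "DH": {"H": -2, "O": -1},
    "halogenation": {"Cl": 1, "H": -1},
}

OFFLOAD_DELTAS: dict[str, dict[str, int]] = {
    "free_acid": {"H": 2, "O": 1},
    "lactone": {},
}


@dataclass
class PredictedProduct:
    formula: dict[str, int]
    provenance: list[str]

    @property
    def halogen_count(self) -> int:
        return self.formula.get("Cl", 0)

    def __str__(self) -> str:
        return formula_to_string(self.formula)


def _apply_delta(formula: dict[str, int], delta: dict[str, int], step: str) -> dict[str, int]:
    out = dict(formula)
    for el, n in delta.items():
        out[el] = out.get(el, 0) + n
        if out[el] < 0:
            raise ValueError(
                f"step {step!r} would make element {el} count negative "
                f"({out[el]}) — chemistry inconsistent with the intermediate"
            )
        if out[el] == 0:
            del out[el]
    return out


def predict_product_formula(
    starter: dict[str, int],
    module_series: list[str],
    offload: str = "free_acid",
    deltas: dict[str, dict[str, int]] | None = None,
) -> PredictedProduct:
    """Apply module deltas in order to a starter formula (collinearity).

    ``module_series`` names operations in :data:`MODULE_DELTAS` (or the
    user-supplied ``deltas`` table); ``offload`` selects the release
    chemistry.  Raises when a delta would drive an element count negative,
    naming the step.
    """
    if not module_series:
        raise ValueError("module series must be non-empty")
    table = deltas if deltas is not None else MODULE_DELTAS
    formula = {el: n for el, n in starter.items() if n}
    if any(n < 0 for n in formula.values()):
        raise ValueError("starter formula has negative counts")
    provenance: list[str] = []
    for step in module_series:
        if step not in table:
            raise ValueError(f"unknown module operation {step!r}")
        formula = _apply_delta(formula, table[step], step)
        provenance.append(step)
    if offload not in OFFLOAD_DELTAS:
        raise ValueError(f"unknown offload chemistry {offload!r}")
    formula = _apply_delta(formula, OFFLOAD_DELTAS[offload], f"offload:{offload}")
    provenance.append(f"offload:{offload}")
    return PredictedProduct(formula=formula, provenance=provenance)
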