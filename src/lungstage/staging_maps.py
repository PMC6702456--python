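"""TNM stage lookup tables for lung adenocarcinoma and squamous cell carcinoma.

Encodes the 8th-edition AJCC/UICC stage grouping at full T/M subdescriptor
granularity (T1a..T4, M0/M1a/M1b/M1c), the coarsened histology x T x N x M
subgroup keys used as clustering units, and the published modified stage
grouping in which adenocarcinoma and squamous cell carcinoma cells of the
same anatomic extent may receive different stages.

Granularity matters: the 8th edition distinguishes T2a (IB with N0) from T2b
(IIA with N0), so the 8th-edition lookup operates on :class:`TNMCategory`
and is coarsened afterwards.  The modified map operates directly on
:class:`SubgroupKey` (T1a/b/c collapsed to T1, T2a/b to T2, M1a/b/c to M1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Iterator, Mapping, Tuple

HISTOLOGIES: Tuple[str, ...] = ("ADC", "SCC")
T_FINE: Tuple[str, ...] = ("T1a", "T1b", "T1c", "T2a", "T2b", "T3", "T4")
T_COARSE: Tuple[str, ...] = ("T1", "T2", "T3", "T4")
N_CATEGORIES: Tuple[str, ...] = ("N0", "N1", "N2", "N3")
M_FINE: Tuple[str, ...] = ("M0", "M1a", "M1b", "M1c")
M_COARSE: Tuple[str, ...] = ("M0", "M1")

SUBSTAGES: Tuple[str, ...] = ("IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IIIC", "IV")
STAGES: Tuple[str, ...] = ("I", "II", "III", "IV")

#: Fixed nesting of sub-stages within stages: (2, 2, 3, 1).
SUBSTAGE_TO_STAGE: Mapping[str, str] = {
    "IA": "I", "IB": "I",
    "IIA": "II", "IIB": "II",
    "IIIA": "III", "IIIB": "III", "IIIC": "III",
    "IV": "IV",
}
STAGE_PATTERN: Tuple[int, ...] = (2, 2, 3, 1)

_T_COARSEN = {"T1a": "T1", "T1b": "T1", "T1c": "T1", "T2a": "T2", "T2b": "T2",
              "T3": "T3", "T4": "T4"}
_M_COARSEN = {"M0": "M0", "M1a": "M1", "M1b": "M1", "M1c": "M1"}


def _check(field: str, value: str, allowed: Tuple[str, ...]) -> None:
    if value not in allowed:
        raise ValueError(
            f"invalid {field} value {value!r}; expected one of {', '.join(allowed)}"
        )


@dataclass(frozen=True)
class TNMCategory:
    """One patient's histology and full-granularity T/N/M classification."""

    histology: str
    t: str
    n: str
    m: str

    def __post_init__(self) -> None:
        _check("histology", self.histology, HISTOLOGIES)
        _check("t", self.t, T_FINE)
        _check("n", self.n, N_CATEGORIES)
        _check("m", self.m, M_FINE)


@dataclass(frozen=True)
class SubgroupKey:
    """Coarse histology x T x N x M clustering unit (T and M subdescriptors collapsed)."""

    histology: str
    t: str
    n: str
    m: str

    def __post_init__(self) -> None:
        _check("histology", self.histology, HISTOLOGIES)
        _check("t", self.t, T_COARSE)
        _check("n", self.n, N_CATEGORIES)
        _check("m", self.m, M_COARSE)

    @property
    def label(self) -> str:
        return f"{self.histology}_{self.t}_{self.n}_{self.m}"

    @classmethod
    def from_label(cls, label: str) -> "SubgroupKey":
        parts = label.split("_")
        if len(parts) != 4:
            raise ValueError(f"malformed subgroup label {label!r}")
        return cls(*parts)


@dataclass(frozen=True)
class StageLabel:
    """A sub-stage together with the stage it nests in."""

    stage: str
    substage: str

    def __post_init__(self) -> None:
        _check("stage", self.stage, STAGES)
        _check("substage", self.substage, SUBSTAGES)
        if SUBSTAGE_TO_STAGE[self.substage] != self.stage:
            raise ValueError(
                f"substage {self.substage} does not nest in stage {self.stage}"
            )

    @classmethod
    def from_substage(cls, substage: str) -> "StageLabel":
        _check("substage", substage, SUBSTAGES)
        return cls(SUBSTAGE_TO_STAGE[substage], substage)

    @property
    def substage_rank(self) -> int:
        return SUBSTAGES.index(self.substage)

    @property
    def stage_rank(self) -> int:
        return STAGES.index(self.stage)


def coarsen(c: TNMCategory) -> SubgroupKey:
    """Collapse T and M subdescriptors (T1a/b/c -> T1, T2a/b -> T2, M1a/b/c -> M1)."""
    return SubgroupKey(c.histology, _T_COARSEN[c.t], c.n, _M_COARSEN[c.m])


# 8th-edition AJCC/UICC stage grouping for M0 disease, keyed on (fine T, N).
# IA1/IA2/IA3 are collapsed to IA; any M1 disease is stage IV.
_EIGHTH_M0: Dict[Tuple[str, str], str] = {
    ("T1a", "N0"): "IA", ("T1b", "N0"): "IA", ("T1c", "N0"): "IA",
    ("T2a", "N0"): "IB", ("T2b", "N0"): "IIA",
    ("T3", "N0"): "IIB", ("T4", "N0"): "IIIA",
    ("T1a", "N1"): "IIB", ("T1b", "N1"): "IIB", ("T1c", "N1"): "IIB",
    ("T2a", "N1"): "IIB", ("T2b", "N1"): "IIB",
    ("T3", "N1"): "IIIA", ("T4", "N1"): "IIIA",
    ("T1a", "N2"): "IIIA", ("T1b", "N2"): "IIIA", ("T1c", "N2"): "IIIA",
    ("T2a", "N2"): "IIIA", ("T2b", "N2"): "IIIA",
    ("T3", "N2"): "IIIB", ("T4", "N2"): "IIIB",
    ("T1a", "N3"): "IIIB", ("T1b", "N3"): "IIIB", ("T1c", "N3"): "IIIB",
    ("T2a", "N3"): "IIIB", ("T2b", "N3"): "IIIB",
    ("T3", "N3"): "IIIC", ("T4", "N3"): "IIIC",
}


def assign_substage_8th(c: TNMCategory) -> StageLabel:
    """8th-edition sub-stage of a fully classified tumour (IA1/2/3 collapsed to IA)."""
    if not isinstance(c, TNMCategory):
        raise TypeError("assign_substage_8th expects a TNMCategory")
    if c.m != "M0":
        return StageLabel.from_substage("IV")
    return StageLabel.from_substage(_EIGHTH_M0[(c.t, c.n)])


# Representative fine subdescriptors used when the 8th edition must be read
# at coarse granularity (defaults for unlisted modified-map cells).  T2 -> T2a
# and M1 -> M1a follow the lower/majority subdescriptor; only the T2 N0 cell
# is actually ambiguous (T2a N0 = IB vs T2b N0 = IIA).
_COARSE_REPRESENTATIVE = {"T1": "T1a", "T2": "T2a", "T3": "T3", "T4": "T4"}


def assign_substage_8th_coarse(k: SubgroupKey) -> StageLabel:
    """8th-edition sub-stage of a coarse subgroup via its representative fine cell."""
    fine = TNMCategory(k.histology, _COARSE_REPRESENTATIVE[k.t], k.n,
                       "M0" if k.m == "M0" else "M1a")
    return assign_substage_8th(fine)


def all_subgroup_keys() -> Iterator[SubgroupKey]:
    """All 64 coarse histology x T x N x M cells."""
    for h in HISTOLOGIES:
        for t in T_COARSE:
            for n in N_CATEGORIES:
                for m in M_COARSE:
                    yield SubgroupKey(h, t, n, m)


def all_tnm_categories() -> Iterator[TNMCategory]:
    """All 112 fine histology x T x N x M cells."""
    for h in HISTOLOGIES:
        for t in T_FINE:
            for n in N_CATEGORIES:
                for m in M_FINE:
                    yield TNMCategory(h, t, n, m)


class MissingStageEntryError(KeyError):
    """A subgroup key has no entry in the stage map (never silently defaulted)."""


@dataclass
class StageMap:
    """Total lookup from subgroup key to stage label under a named system.

    ``granularity`` is ``"coarse"`` for maps keyed on :class:`SubgroupKey`
    (the modified systems) or ``"fine"`` for maps keyed on
    :class:`TNMCategory` (the 8th edition, where T2a vs T2b matters).
    ``sources`` records the provenance of each entry: ``"paper"`` for cells
    fixed by the published reassignment statements, ``"default"`` for cells
    falling back to the 8th-edition assignment, ``"derived"`` for cells
    produced by the clustering pipeline.
    """

    system_name: str
    entries: Dict
    sources: Dict
    granularity: str = "coarse"

    def lookup(self, key) -> StageLabel:
        try:
            return self.entries[key]
        except KeyError:
            label = getattr(key, "label", None) or (
                f"{key.histology}_{key.t}_{key.n}_{key.m}")
            raise MissingStageEntryError(
                f"stage map {self.system_name!r} has no entry for subgroup "
                f"{label}; refusing to fall through to another system"
            ) from None

    def stage_of_category(self, c: TNMCategory) -> StageLabel:
        """Stage a fully classified tumour, coarsening first if needed."""
        if self.granularity == "fine":
            return self.lookup(c)
        return self.lookup(coarsen(c))

    def source(self, key) -> str:
        return self.sources.get(key, "unknown")

    def to_json(self) -> str:
        records = [
            {
                "histology": k.histology, "t": k.t, "n": k.n, "m": k.m,
                "stage": v.stage, "substage": v.substage,
                "source": self.sources.get(k, "unknown"),
            }
            for k, v in sorted(self.entries.items(),
                               key=lambda kv: (kv[0].histology, kv[0].t,
                                               kv[0].n, kv[0].m))
        ]
        return json.dumps({"system": self.system_name,
                           "granularity": self.granularity,
                           "entries": records}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StageMap":
        payload = json.loads(text)
        granularity = payload.get("granularity", "coarse")
        key_cls = TNMCategory if granularity == "fine" else SubgroupKey
        entries: Dict = {}
        sources: Dict = {}
        for rec in payload["entries"]:
            key = key_cls(rec["histology"], rec["t"], rec["n"], rec["m"])
            entries[key] = StageLabel(rec["stage"], rec["substage"])
            sources[key] = rec.get("source", "unknown")
        return cls(payload["system"], entries, sources, granularity)


def assign_substage_modified(k: SubgroupKey, stage_map: StageMap) -> StageLabel:
    """Pure lookup of a coarse subgroup in a modified stage map."""
    return stage_map.lookup(k)


# Published reassignments of M0 cells, keyed (histology, coarse T, N).
# Adenocarcinoma moves down (better outcomes), squamous cell carcinoma T1-2 N0
# moves up (worse outcomes); unlisted cells keep their 8th-edition assignment.
PAPER_REASSIGNMENTS: Dict[Tuple[str, str, str], str] = {
    ("ADC", "T1", "N1"): "IB",
    ("ADC", "T1", "N2"): "IIA",
    ("ADC", "T2", "N1"): "IIA",
    ("ADC", "T3", "N0"): "IIA",
    ("ADC", "T4", "N0"): "IIB",
    ("ADC", "T3", "N1"): "IIB",
    ("ADC", "T4", "N1"): "IIB",
    ("ADC", "T2", "N2"): "IIB",
    ("ADC", "T3", "N2"): "IIIA",
    ("ADC", "T4", "N2"): "IIIA",
    ("ADC", "T2", "N3"): "IIIA",
    ("ADC", "T3", "N3"): "IIIB",
    ("ADC", "T4", "N3"): "IIIB",
    ("SCC", "T1", "N0"): "IB",
    ("SCC", "T2", "N0"): "IIA",
}


def eighth_edition_coarse_map() -> StageMap:
    """8th-edition grouping read at coarse subgroup granularity (all 64 cells)."""
    entries = {k: assign_substage_8th_coarse(k) for k in all_subgroup_keys()}
    sources = {k: "default" for k in entries}
    return StageMap("eighth_edition_coarse", entries, sources)


def eighth_edition_map() -> StageMap:
    """8th-edition grouping at full TNM granularity (all 112 fine cells)."""
    entries = {c: assign_substage_8th(c) for c in all_tnm_categories()}
    sources = {c: "default" for c in entries}
    return StageMap("eighth_edition", entries, sources, granularity="fine")


def paper_modified_map() -> StageMap:
    """The published modified stage grouping over all 64 coarse cells.

    Cells fixed by an explicit reassignment statement carry source
    ``"paper"``; every other cell (including all M1 cells, whose partial
    shift toward IIIB/IIIC is not resolvable to specific subcategories)
    defaults to the 8th-edition assignment with source ``"default"``.
    """
    entries: Dict[SubgroupKey, StageLabel] = {}
    sources: Dict[SubgroupKey, str] = {}
    for k in all_subgroup_keys():
        move = PAPER_REASSIGNMENTS.get((k.histology, k.t, k.n))
        if k.m == "M0" and move is not None:
            entries[k] = StageLabel.from_substage(move)
            sources[k] = "paper"
        else:
            entries[k] = assign_substage_8th_coarse(k)
            sources[k] = "default"
    return StageMap("paper_modified", entries, sources)
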