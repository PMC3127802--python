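"""The CA1 dendrite+spine signaling model: species, reactions, initial
conditions, and the spatial anchoring configurations.

The model content lives in declarative YAML files under ``spinerd/data``:
``species.yaml`` (names, diffusion constants, moiety compositions),
``reactions.yaml`` (table rows with kf/kb/kcat) and
``initial_conditions.yaml`` (basal concentrations plus the assumed anchored
quantities).  ``build_model`` parses them into a :class:`ModelSpec`; each
printed table row expands into elementary mass-action reactions (binding,
unbinding, catalysis).

Anchoring (``apply_anchoring``) restricts the dopamine receptor, G protein,
adenylyl cyclase and PKA holoenzyme to the spine head compartment or to a
focal dendritic submembrane region of equal local concentration, following
the AKAP-anchoring hypotheses under study; GluR1 always sits in the PSD and
the calcium pumps in membrane-adjacent voxels.  Anchoring only moves
molecules: totals are identical across configurations.
"""

from __future__ import annotations

import copy
import hashlib
import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal

import numpy as np
import yaml

from .mesh import Mesh, Region

# 1 nM in 1 um^3 corresponds to this many molecules (N_A * 1e-15 L * 1e-9 M)
NAV = 0.602214076


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    diffusion_constant: float  # um^2/s, 0 = anchored / non-diffusing
    composition: dict[str, int] = field(default_factory=dict)
    tags: tuple[str, ...] = ()
    clamped: bool = False

    def __post_init__(self):
        if self.diffusion_constant < 0:
            raise ValueError(f"{self.name}: diffusion constant must be >= 0")


@dataclass(frozen=True)
class ReactionSpec:
    """One elementary mass-action reaction.

    ``rate_constant`` is in s^-1 for unimolecular reactions and nM^-1 s^-1
    for bimolecular ones.  ``reactants`` lists (species, consumed count);
    the propensity is k*n_A for unimolecular, k_conv*n_A*n_B for A+B (and
    A+2B) events and k_conv*n_A*(n_A-1) for homodimerizations.
    """

    name: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant: float

    def __post_init__(self):
        if self.rate_constant < 0:
            raise ValueError(f"{self.name}: rate constant must be >= 0")
        n_distinct = len(self.reactants)
        if n_distinct not in (1, 2):
            raise ValueError(f"{self.name}: reactions must have 1 or 2 reactant species")

    @property
    def order(self) -> int:
        return len(self.reactants)

    @property
    def homodimer(self) -> bool:
        return len(self.reactants) == 1 and self.reactants[0][1] == 2


@dataclass(frozen=True)
class TableRow:
    """A printed reaction-table row (possibly an enzyme triple)."""

    eq: str
    kf: float | None
    kb: float | None
    kcat: float | None
    table: str


@dataclass(frozen=True)
class AnchoringConfig:
    """Spatial placement of PKA and adenylyl cyclase (D1R and G proteins
    always colocalize with AC; GluR1 is always in the PSD)."""

    pka_location: Literal["spine", "dendrite_focal", "uniform"] = "spine"
    ac_location: Literal["spine", "dendrite_focal"] = "spine"

    @property
    def label(self) -> str:
        return f"pka_{self.pka_location}__ac_{self.ac_location}"


@dataclass
class ModelSpec:
    species: list[SpeciesSpec]
    rows: list[TableRow]
    initial_conditions_nM: dict[str, float]  # general cytosol, nM
    anchored_molecules: dict[str, float]  # assumed totals, molecules
    pump_density_per_um2: dict[str, float]  # assumed membrane densities
    variant: str = "default"
    # filled by apply_anchoring: species -> per-voxel integer counts
    anchored_counts: dict[str, np.ndarray] = field(default_factory=dict)
    anchoring: AnchoringConfig | None = None

    # -- lookups ----------------------------------------------------------
    def species_map(self) -> dict[str, SpeciesSpec]:
        return {s.name: s for s in self.species}

    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def diffusion_constant(self, name: str) -> float:
        return self.species_map()[name].diffusion_constant

    def initial_concentration(self, name: str) -> float:
        return self.initial_conditions_nM.get(name, 0.0)

    def rates(self, eq: str) -> tuple[float | None, float | None, float | None]:
        """Verbatim (kf, kb, kcat) of a printed table row, by equation."""
        key = _normalize_eq(eq)
        for row in self.rows:
            if _normalize_eq(row.eq) == key:
                return (row.kf, row.kb, row.kcat)
        raise KeyError(f"no reaction row matching {eq!r}")

    def elementary(self) -> list[ReactionSpec]:
        out: list[ReactionSpec] = []
        for i, row in enumerate(self.rows):
            out.extend(_expand_row(row, f"r{i:03d}"))
        return out

    def tagged_species(self, tag: str) -> list[str]:
        return [s.name for s in self.species if tag in s.tags]

    def moiety_species(self, moiety: str) -> dict[str, int]:
        """Species carrying >=1 unit of an elementary moiety, with weights."""
        out = {}
        for s in self.species:
            w = s.composition.get(moiety, 0)
            if w:
                out[s.name] = w
        return out

    def moieties(self) -> list[str]:
        names: set[str] = set()
        for s in self.species:
            names.update(s.composition)
        return sorted(names)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "species": [
                {
                    "name": s.name,
                    "D": s.diffusion_constant,
                    "composition": dict(s.composition),
                    "tags": list(s.tags),
                    "clamped": s.clamped,
                }
                for s in self.species
            ],
            "reactions": [
                {"eq": r.eq, "kf": r.kf, "kb": r.kb, "kcat": r.kcat, "table": r.table}
                for r in self.rows
            ],
            "general_cytosol_nM": dict(self.initial_conditions_nM),
            "anchored_molecules": dict(self.anchored_molecules),
            "pump_density_per_um2": dict(self.pump_density_per_um2),
        }

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


# --------------------------------------------------------------------------
# equation parsing
# --------------------------------------------------------------------------

def _normalize_eq(eq: str) -> str:
    return re.sub(r"\s+", " ", eq.strip())


def _parse_side(side: str) -> list[tuple[str, int]]:
    terms: list[tuple[str, int]] = []
    for term in side.split("+"):
        term = term.strip()
        m = re.fullmatch(r"(?:(\d+)\s+)?([A-Za-z0-9_]+)", term)
        if not m:
            raise ValueError(f"cannot parse reaction term {term!r}")
        terms.append((m.group(2), int(m.group(1) or 1)))
    # merge duplicates (e.g. "Complex + Complex")
    merged: dict[str, int] = {}
    order: list[str] = []
    for name, n in terms:
        if name not in merged:
            merged[name] = 0
            order.append(name)
        merged[name] += n
    return [(name, merged[name]) for name in order]


def _expand_row(row: TableRow, rid: str) -> list[ReactionSpec]:
    eq = _normalize_eq(row.eq)
    out: list[ReactionSpec] = []

    def mk(suffix, lhs, rhs, k):
        return ReactionSpec(
            name=f"{rid}_{suffix}", reactants=tuple(lhs), products=tuple(rhs),
            rate_constant=float(k),
        )

    if "<->" in eq:
        left, rest = [p.strip() for p in eq.split("<->", 1)]
        if "->" in rest:  # enzyme triple: A + B <-> ES -> products
            mid, rhs = [p.strip() for p in rest.split("->", 1)]
            lhs_t, mid_t, rhs_t = _parse_side(left), _parse_side(mid), _parse_side(rhs)
            out.append(mk("bind", lhs_t, mid_t, row.kf))
            if row.kb is not None:
                out.append(mk("unbind", mid_t, lhs_t, row.kb))
            out.append(mk("cat", mid_t, rhs_t, row.kcat))
        else:  # reversible pair
            lhs_t, rhs_t = _parse_side(left), _parse_side(rest)
            out.append(mk("f", lhs_t, rhs_t, row.kf))
            out.append(mk("b", rhs_t, lhs_t, row.kb))
    else:
        left, rhs = [p.strip() for p in eq.split("->", 1)]
        k = row.kf if row.kf is not None else row.kcat
        out.append(mk("f", _parse_side(left), _parse_side(rhs), k))
    return out


# --------------------------------------------------------------------------
# model construction
# --------------------------------------------------------------------------

def _load_yaml(name: str):
    ref = resources.files("spinerd.data").joinpath(name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def build_model() -> ModelSpec:
    """Build the full model from the shipped declarative files."""
    species_raw = _load_yaml("species.yaml")
    reactions_raw = _load_yaml("reactions.yaml")
    ic_raw = _load_yaml("initial_conditions.yaml")

    species = [
        SpeciesSpec(
            name=s["name"],
            diffusion_constant=float(s.get("D", 0.0)),
            composition={k: int(v) for k, v in (s.get("composition") or {}).items()},
            tags=tuple(s.get("tags", ())),
            clamped=bool(s.get("clamped", False)),
        )
        for s in species_raw
    ]
    names = [s.name for s in species]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate species: {dupes}")

    rows = [
        TableRow(
            eq=_normalize_eq(r["eq"]),
            kf=None if r.get("kf") is None else float(r["kf"]),
            kb=None if r.get("kb") is None else float(r["kb"]),
            kcat=None if r.get("kcat") is None else float(r["kcat"]),
            table=r.get("table", ""),
        )
        for r in reactions_raw
    ]
    eqs = [_normalize_eq(r.eq) for r in rows]
    if len(set(eqs)) != len(eqs):
        dupes = sorted({e for e in eqs if eqs.count(e) > 1})
        raise ValueError(f"duplicate reaction rows: {dupes}")

    model = ModelSpec(
        species=species,
        rows=rows,
        initial_conditions_nM={k: float(v) for k, v in ic_raw["general_cytosol_nM"].items()},
        anchored_molecules={k: float(v) for k, v in ic_raw["anchored_molecules"].items()},
        pump_density_per_um2={k: float(v) for k, v in ic_raw["pump_density_per_um2"].items()},
    )
    findings = validate_model(model)["errors"]
    if findings:
        raise ValueError("model failed validation: " + "; ".join(findings))
    return model


def model_from_dict(d: dict) -> ModelSpec:
    """Inverse of :meth:`ModelSpec.to_dict` (lossless round trip)."""
    species = [
        SpeciesSpec(
            name=s["name"],
            diffusion_constant=float(s["D"]),
            composition={k: int(v) for k, v in s["composition"].items()},
            tags=tuple(s["tags"]),
            clamped=bool(s["clamped"]),
        )
        for s in d["species"]
    ]
    rows = [
        TableRow(eq=r["eq"], kf=r["kf"], kb=r["kb"], kcat=r["kcat"], table=r["table"])
        for r in d["reactions"]
    ]
    return ModelSpec(
        species=species,
        rows=rows,
        initial_conditions_nM=dict(d["general_cytosol_nM"]),
        anchored_molecules=dict(d["anchored_molecules"]),
        pump_density_per_um2=dict(d["pump_density_per_um2"]),
        variant=d.get("variant", "default"),
    )


# --------------------------------------------------------------------------
# variants
# --------------------------------------------------------------------------

_PP1_GLUR1_ROWS = (
    "pS845GluR1 + PP1 <-> pS845GluR1_PP1 -> GluR1 + PP1",
    "pS845pS831GluR1 + PP1 <-> pS845pS831GluR1_PP1 -> pS831GluR1 + PP1",
    "pS831GluR1 + PP1 <-> pS831GluR1_PP1 -> GluR1 + PP1",
)


def apply_variant(
    model: ModelSpec,
    variant: str,
    *,
    diffusion_scale: float = 2.0,
    pp1_kcat_factor: float = 0.5,
) -> ModelSpec:
    """Parameter variants used for robustness checks.

    ``fast_diffusion``: cAMP diffusion to the in-vitro-like 172.8 um^2/s and
    the other diffusible species scaled by ``diffusion_scale``.
    ``slow_pp1_glur1``: kcat of the PP1 dephosphorylation of GluR1 scaled by
    ``pp1_kcat_factor``.
    """
    if variant == "default":
        return model
    m = copy.deepcopy(model)
    m.variant = variant
    if variant == "fast_diffusion":
        m.species = [
            replace(
                s,
                diffusion_constant=(
                    172.8 if s.name == "cAMP"
                    else s.diffusion_constant * diffusion_scale
                ),
            )
            if s.diffusion_constant > 0
            else s
            for s in m.species
        ]
    elif variant == "slow_pp1_glur1":
        keys = {_normalize_eq(e) for e in _PP1_GLUR1_ROWS}
        m.rows = [
            replace(r, kcat=r.kcat * pp1_kcat_factor)
            if _normalize_eq(r.eq) in keys
            else r
            for r in m.rows
        ]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return m


# --------------------------------------------------------------------------
# anchoring
# --------------------------------------------------------------------------

def pka_basal_fractions(model: ModelSpec) -> dict[str, float]:
    """Basal split of the PKA holoenzyme pool across its cAMP-binding ladder,
    in equilibrium with the printed basal cAMP concentration.

    The printed basal state includes PKAc-bound complexes (I1PKAc,
    PKAcPDE4B/D), which presuppose a partially cAMP-loaded PKA pool; an
    all-apo holoenzyme start would contradict them.  Fractions follow the
    printed association/dissociation constants at the printed basal cAMP.
    """
    camp = model.initial_concentration("cAMP")
    kf1, kb1, _ = model.rates("PKA + 2 cAMP <-> PKAcAMP2")
    kf2, kb2, _ = model.rates("PKAcAMP2 + 2 cAMP <-> PKAcAMP4")
    f2 = (kf1 / kb1) * camp
    f4 = f2 * (kf2 / kb2) * camp
    z = 1.0 + f2 + f4
    return {"PKA": 1.0 / z, "PKAcAMP2": f2 / z, "PKAcAMP4": f4 / z}


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Deterministic largest-remainder split of ``total`` molecules over
    voxels proportionally to ``weights``; exact total, reproducible."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("cannot apportion over zero total weight")
    exact = total * w / w.sum()
    base = np.floor(exact).astype(np.int64)
    short = int(total - base.sum())
    if short:
        frac = exact - base
        order = np.lexsort((np.arange(len(w)), -frac))
        base[order[:short]] += 1
    return base


def apply_anchoring(model: ModelSpec, mesh: Mesh, config: AnchoringConfig) -> ModelSpec:
    """Place the anchored species on the mesh per the 2x2 (+uniform) design.

    D1R ("R"), G protein and AC1/AC8 colocalize at ``ac_location``; the PKA
    holoenzyme goes to ``pka_location`` ("uniform" spreads it over all voxels
    volume-proportionally, emulating Ht31 disruption of anchoring); GluR1 is
    restricted to the PSD and the pumps to membrane-adjacent voxels.  Total
    molecule numbers are identical across configurations.
    """
    sets = mesh.metadata.get("sets", {})
    if "spine_head_compartment" not in sets:
        raise ValueError("mesh lacks a spine_head_compartment voxel set")
    needs_focal = "dendrite_focal" in (config.pka_location, config.ac_location)
    if needs_focal and "focal_dendrite" not in sets:
        raise ValueError("anchoring config requests a focal dendritic region "
                         "but the mesh has none")

    volumes = mesh.volumes()
    n = mesh.n_voxels

    def region_weights(idxs):
        w = np.zeros(n)
        w[list(idxs)] = volumes[list(idxs)]
        return w

    loc_sets = {
        "spine": sets["spine_head_compartment"],
        "dendrite_focal": sets.get("focal_dendrite", []),
    }

    m = copy.deepcopy(model)
    m.anchoring = config
    m.anchored_counts = {}

    # anchored totals are defined for the single-spine morphology; on a
    # multi-spine mesh they scale with the number of spines so that the
    # local (per-spine-head) concentrations are unchanged
    n_spines = (
        mesh.metadata.get("params", {}).get("n_spines", 1)
        if mesh.metadata.get("kind") == "multi_spine"
        else 1
    )

    ac_w = region_weights(loc_sets[config.ac_location])
    for sp in ("R", "Gabg", "AC1", "AC8"):
        m.anchored_counts[sp] = _apportion(
            int(m.anchored_molecules[sp]) * n_spines, ac_w
        )

    if config.pka_location == "uniform":
        pka_w = volumes.copy()
    else:
        pka_w = region_weights(loc_sets[config.pka_location])
    # the holoenzyme pool starts in equilibrium with the printed basal cAMP
    pka_total = int(m.anchored_molecules["PKA"]) * n_spines
    fractions = pka_basal_fractions(m)
    split = {sp: int(round(f * pka_total)) for sp, f in fractions.items()}
    split["PKA"] += pka_total - sum(split.values())
    for sp, count in split.items():
        m.anchored_counts[sp] = _apportion(count, pka_w)

    psd = sets.get("psd")
    if not psd:
        raise ValueError("mesh lacks a psd voxel set")
    m.anchored_counts["GluR1"] = _apportion(
        int(m.anchored_molecules["GluR1"]) * n_spines, region_weights(psd)
    )

    areas = np.array([v.membrane_area for v in mesh.voxels])
    total_area = areas.sum()
    for pump, dens in m.pump_density_per_um2.items():
        m.anchored_counts[pump] = _apportion(int(round(dens * total_area)), areas)
    return m


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def validate_model(model: ModelSpec) -> dict:
    """Machine-readable integrity report.

    Checks that every reaction species is declared, that rates are
    nonnegative, and that every elementary reaction conserves every
    elementary moiety (the conservation report lists, per moiety, the
    species carrying it).  Returns {"errors": [...], "warnings": [...],
    "moieties": {moiety: {species: weight}}}.
    """
    errors: list[str] = []
    warnings: list[str] = []
    smap = model.species_map()

    for row in model.rows:
        for k, v in (("kf", row.kf), ("kb", row.kb), ("kcat", row.kcat)):
            if v is not None and v < 0:
                errors.append(f"{row.eq}: negative {k}")

    try:
        elem = model.elementary()
    except Exception as exc:  # parse failures are fatal findings
        return {"errors": [str(exc)], "warnings": [], "moieties": {}}

    for rx in elem:
        for name, _ in rx.reactants + rx.products:
            if name not in smap:
                errors.append(f"{rx.name}: undeclared species {name}")

    # moiety conservation, from compositions
    moieties = {m: model.moiety_species(m) for m in model.moieties()}
    for rx in elem:
        bad = set()
        for moiety, weights in moieties.items():
            lhs = sum(weights.get(s, 0) * c for s, c in rx.reactants if s in smap)
            rhs = sum(weights.get(s, 0) * c for s, c in rx.products if s in smap)
            if lhs != rhs:
                bad.add(moiety)
        if bad:
            errors.append(f"{rx.name}: does not conserve {sorted(bad)}")

    for sp, conc in model.initial_conditions_nM.items():
        if sp not in smap:
            errors.append(f"initial condition for undeclared species {sp}")
        elif conc < 0:
            errors.append(f"negative initial concentration for {sp}")

    for sp in model.anchored_molecules:
        if sp not in smap:
            errors.append(f"anchored quantity for undeclared species {sp}")
        elif smap[sp].diffusion_constant != 0:
            errors.append(f"anchored species {sp} has nonzero diffusion constant")

    return {"errors": errors, "warnings": warnings, "moieties": moieties}
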