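"""Site configuration container and YAML/CSV round-trip.

A :class:`Site` bundles everything a projection run needs: the reach network,
raw PCB sources (upstream springs, NSB seeps), the spring treatment facility
(STF) description, fate/transport parameters, initial bed state, food-web
parameters, monitoring stations and compliance targets, plus the boundary
flow record.  ``to_dir``/``from_dir`` write and read a plain-text run
directory (site.yml + flows.csv) with deterministic formatting so a fixture
regenerated from the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .channel_hydro import Network, Reach
from .fate_transport import BedState, FateParams
from .foodweb_bioacc import InvertebrateParams, SpeciesParams
from .rcc_stats import RCCSpec
from .source_loading import SourceSpec

__all__ = ["Station", "STFConfig", "Site"]

DAYS_PER_YEAR = 365


@dataclass
class Station:
    """A monitoring station: river mile, species sampled, reporting basis."""

    name: str
    mile: float
    species: tuple
    basis: str = "whole_body"


@dataclass
class STFConfig:
    """Spring treatment facility: interception, treatment, optional storage.

    capture_fraction is the share of spring base/storm flow the collection
    system can physically intercept; capacity_gpm limits treatment throughput;
    excess intercepted flow fills the storage basin (fill-spill) and is
    treated as capacity frees up.  Treatment removes ``efficiency`` of the
    PCB mass in treated water; effluent discharges at ``outfall_mile``.
    """

    active: bool = True
    capacity_gpm: float = 450.0
    storage_gal: float = 0.0
    efficiency: float = 0.99
    outfall_mile: float = 0.12
    capture_fraction: float = 0.85


@dataclass
class Site:
    """Complete model configuration for one site realization."""

    reaches: list
    spring: SourceSpec
    nsb: SourceSpec
    stf: STFConfig
    fate: FateParams
    bed_conc: dict                 # reach id -> initial active/deep conc (mg/kg)
    species: dict                  # species name -> SpeciesParams
    inverts: InvertebrateParams
    stations: list
    rcc: RCCSpec
    flows: pd.DataFrame            # daily boundary flows (m3/s)
    start_year: float = 2001.0
    rc_confluence_mile: float = 0.8
    fillet_ratio: float = 0.35
    post_dredge_conc: float = 1.0
    tss_rating: dict = field(default_factory=lambda: {
        "cb_spring": (5.0, 0.5, 0.02),
        "rc_upstream": (5.0, 0.5, 0.16),
        "nsb": (5.0, 0.5, 0.004),
    })
    bed_props: dict = field(default_factory=lambda: dict(
        thickness_active=0.05, thickness_deep=0.15, porosity=0.5,
        bulk_density=1.25, foc=0.04))

    def network(self, inflow_miles: dict) -> Network:
        return Network(list(self.reaches), dict(inflow_miles))

    def build_bed(self, network: Network, dredged_reaches=()) -> BedState:
        conc = np.zeros(network.n_cells)
        for reach in self.reaches:
            c0 = self.bed_conc[reach.id]
            if reach.id in dredged_reaches:
                c0 = self.post_dredge_conc
            sel = (network.mile >= reach.start_mile) & (network.mile <= reach.end_mile)
            conc[sel] = c0
        bp = self.bed_props
        n = network.n_cells
        full = lambda v: np.full(n, float(v))
        return BedState(full(bp["thickness_active"]), full(bp["thickness_deep"]),
                        full(bp["porosity"]), full(bp["bulk_density"]),
                        full(bp["foc"]), conc, conc.copy())

    def times_yr(self, n_days: int | None = None) -> np.ndarray:
        n = len(self.flows) if n_days is None else n_days
        return self.start_year + np.arange(n) / DAYS_PER_YEAR

    def boundary_tss(self, flows: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for label, (a, b, qref) in self.tss_rating.items():
            q = flows[label].to_numpy(dtype=float)
            with np.errstate(divide="ignore"):
                out[label] = np.where(q > 0, np.minimum(a * (q / qref) ** b, 300.0), 0.0)
        return pd.DataFrame(out, index=flows.index)

    # ------------------------------------------------------------------ IO
    def to_dir(self, path):
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        doc = {
            "reaches": [dataclasses.asdict(r) for r in self.reaches],
            "spring": _source_doc(self.spring),
            "nsb": _source_doc(self.nsb),
            "stf": dataclasses.asdict(self.stf),
            "fate": dataclasses.asdict(self.fate),
            "bed_conc": dict(self.bed_conc),
            "bed_props": dict(self.bed_props),
            "species": {k: _species_doc(v) for k, v in self.species.items()},
            "inverts": dataclasses.asdict(self.inverts),
            "stations": [dict(name=s.name, mile=s.mile, species=list(s.species),
                              basis=s.basis) for s in self.stations],
            "rcc": {"targets": {k: list(v) for k, v in self.rcc.targets.items()},
                    "alpha": self.rcc.alpha,
                    "review_interval_yr": self.rcc.review_interval_yr},
            "start_year": self.start_year,
            "rc_confluence_mile": self.rc_confluence_mile,
            "fillet_ratio": self.fillet_ratio,
            "post_dredge_conc": self.post_dredge_conc,
            "tss_rating": {k: list(v) for k, v in self.tss_rating.items()},
        }
        (path / "site.yml").write_text(
            yaml.safe_dump(_plain(doc), sort_keys=True, default_flow_style=False))
        self.flows.to_csv(path / "flows.csv", index_label="day",
                          float_format="%.8g")

    @classmethod
    def from_dir(cls, path) -> "Site":
        path = Path(path)
        doc = yaml.safe_load((path / "site.yml").read_text())
        flows = pd.read_csv(path / "flows.csv", index_col="day")
        reaches = [Reach(**r) for r in doc["reaches"]]
        return cls(
            reaches=reaches,
            spring=_source_from(doc["spring"]),
            nsb=_source_from(doc["nsb"]),
            stf=STFConfig(**doc["stf"]),
            fate=FateParams(**doc["fate"]),
            bed_conc=doc["bed_conc"],
            species={k: _species_from(v) for k, v in doc["species"].items()},
            inverts=InvertebrateParams(**doc["inverts"]),
            stations=[Station(name=s["name"], mile=s["mile"],
                              species=tuple(s["species"]), basis=s["basis"])
                      for s in doc["stations"]],
            rcc=RCCSpec(targets={k: tuple(v) for k, v in doc["rcc"]["targets"].items()},
                        alpha=doc["rcc"]["alpha"],
                        review_interval_yr=doc["rcc"]["review_interval_yr"]),
            flows=flows,
            start_year=doc["start_year"],
            rc_confluence_mile=doc["rc_confluence_mile"],
            fillet_ratio=doc["fillet_ratio"],
            post_dredge_conc=doc["post_dredge_conc"],
            tss_rating={k: tuple(v) for k, v in doc["tss_rating"].items()},
            bed_props=doc["bed_props"],
        )


def _source_doc(s: SourceSpec) -> dict:
    d = dataclasses.asdict(s)
    d["regimes"] = {k: list(v) for k, v in s.regimes.items()}
    if d["storm_threshold"] == np.inf:
        d["storm_threshold"] = "inf"
    return d


def _source_from(d: dict) -> SourceSpec:
    d = dict(d)
    d["regimes"] = {k: tuple(v) for k, v in d["regimes"].items()}
    if d["storm_threshold"] == "inf":
        d["storm_threshold"] = np.inf
    return SourceSpec(**d)


def _species_doc(sp: SpeciesParams) -> dict:
    d = dataclasses.asdict(sp)
    d["lipid_by_month"] = [float(x) for x in sp.lipid_by_month]
    d["diet_by_month"] = [list(x) for x in sp.diet_by_month]
    d["weight_at_age"] = list(sp.weight_at_age)
    d["age_classes"] = list(sp.age_classes)
    d["respiration"] = list(sp.respiration)
    return d


def _species_from(d: dict) -> SpeciesParams:
    d = dict(d)
    d["lipid_by_month"] = tuple(d["lipid_by_month"])
    d["diet_by_month"] = tuple(tuple(x) for x in d["diet_by_month"])
    d["weight_at_age"] = tuple(d["weight_at_age"])
    d["age_classes"] = tuple(d["age_classes"])
    d["respiration"] = tuple(d["respiration"])
    return SpeciesParams(**d)


def _plain(obj):
    """Recursively convert numpy scalars for stable YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
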