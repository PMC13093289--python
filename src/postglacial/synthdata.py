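"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators stand in for the study's external inputs: multi-population
mitochondrial alignments simulated under a known demographic scenario (with
the true parameter values recorded in a truth file), herd coordinate
tables, and gridded monthly sea-ice fields built from a known closed form
(linear trend over time, seasonal cosine, spatial gradient, Gaussian
noise, land mask).

Every artifact round-trips through the package's own readers, and truth
files are first-class outputs so recovery tests never re-derive ground
truth from logs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import coalsim
from .icecompare import MONTHS, HerdLocations, IceField, LaeaProjection
from .scenarios import DemographicScenario, ParameterDraw, Prior, sample_parameters
from .seqdata import Alignment


# --------------------------------------------------------------------------
# scenario builders (shipped example model sets use these)
# --------------------------------------------------------------------------


def well_separated_pair(
    t_recent: float = 50.0,
    t_deep: float = 5000.0,
    ne: float = 1000.0,
    n_per_pop: int = 10,
    mu: float = 1e-5,
    time_prior: tuple[float, float] = (10.0, 10000.0),
) -> list[DemographicScenario]:
    """Two-scenario model set differing only in divergence depth.

    The canonical self-consistency testbed: two populations of haploid size
    ``ne`` that diverged either recently (``t_recent``) or deeply
    (``t_deep``); each scenario puts a tight prior around its own truth so
    the scenarios are well separated in summary-statistic space.
    """

    def make(sid: str, t: float) -> DemographicScenario:
        return DemographicScenario(
            id=sid,
            populations=[
                _pop("A", (ne * 0.5, ne * 2.0), n_per_pop),
                _pop("B", (ne * 0.5, ne * 2.0), n_per_pop),
            ],
            events=[
                _div("split", ("B", "A"), (t * 0.5, t * 2.0)),
            ],
            mutation={"mu": mu, "kappa": 4.0, "alpha": 0.5, "p_inv": 0.3,
                      "pi": [0.3, 0.2, 0.15, 0.35]},
        )

    return [make("recent", t_recent), make("deep", t_deep)]


def _pop(label, ne, n, age: int = 0):
    from .scenarios import PopulationSpec

    return PopulationSpec(label=label, ne=Prior.of(ne), sample_size=n, sampling_age=age)


def _div(name, parts, t):
    from .scenarios import DemographicEvent

    return DemographicEvent(kind="divergence", name=name, participants=parts,
                            time=Prior.of(t))


def _admix(name, parts, t, r):
    from .scenarios import DemographicEvent

    return DemographicEvent(kind="admixture", name=name, participants=parts,
                            time=Prior.of(t), rate=Prior.of(r))


def _bottleneck(name, pop, nb, db=(1, 50)):
    from .scenarios import DemographicEvent

    return DemographicEvent(kind="bottleneck", name=name, participants=(pop,),
                            nb=Prior.of(nb), duration=Prior.of(db))


_MUT_CR = {"mu": (1e-6, 1e-5), "kappa": (2.0, 20.0), "alpha": 0.5, "p_inv": 0.4,
           "pi": [0.31, 0.21, 0.14, 0.34]}


def naai_like_model_set() -> list[DemographicScenario]:
    """Four-scenario model set mirroring the final North American Arctic
    island configuration: West Greenland, Canadian Arctic Archipelago (CAA),
    mainland, and a combined East Greenland & Banks-Melville group, with
    founder bottlenecks in West Greenland and East Greenland & Banks-Melville.
    Priors are illustrative placeholders, not the study's.
    """
    pops = lambda: [  # noqa: E731
        _pop("WestGreenland", (500, 20000), 40),
        _pop("CAA", (1000, 50000), 80),
        _pop("Mainland", (5000, 100000), 80),
        _pop("EG_BanksMelville", (500, 20000), 40),
    ]
    common = dict(mutation=dict(_MUT_CR))

    s1 = DemographicScenario(
        id="naai1_no_admixture",
        populations=pops(),
        events=[
            _div("egbm", ("EG_BanksMelville", "CAA"), (50, 1500)),
            _div("wg", ("WestGreenland", "Mainland"), (50, 1500)),
            _div("caa", ("CAA", "Mainland"), (500, 3000)),
            _bottleneck("egbm_founder", "EG_BanksMelville", (10, 500)),
            _bottleneck("wg_founder", "WestGreenland", (10, 500)),
        ],
        order_constraints=[("caa", "egbm")],
        **common,
    )
    s2 = DemographicScenario(
        id="naai2_admixture",
        populations=pops(),
        events=[
            _div("egbm", ("EG_BanksMelville", "CAA"), (50, 1500)),
            _div("wg", ("WestGreenland", "Mainland"), (50, 1500)),
            _div("caa", ("CAA", "Mainland"), (500, 3000)),
            _admix("mainland_into_caa", ("CAA", "Mainland"), (50, 1000), (0.05, 0.5)),
            _bottleneck("egbm_founder", "EG_BanksMelville", (10, 500)),
            _bottleneck("wg_founder", "WestGreenland", (10, 500)),
        ],
        order_constraints=[("caa", "egbm"), ("caa", "mainland_into_caa")],
        **common,
    )
    s3 = DemographicScenario(
        id="naai3_egbm_from_mainland",
        populations=pops(),
        events=[
            _div("egbm", ("EG_BanksMelville", "Mainland"), (50, 1500)),
            _div("wg", ("WestGreenland", "Mainland"), (50, 1500)),
            _div("caa", ("CAA", "Mainland"), (500, 3000)),
            _bottleneck("egbm_founder", "EG_BanksMelville", (10, 500)),
            _bottleneck("wg_founder", "WestGreenland", (10, 500)),
        ],
        **common,
    )
    s4 = DemographicScenario(
        id="naai4_glacial_divergence",
        populations=pops(),
        events=[
            _div("egbm", ("EG_BanksMelville", "CAA"), (50, 1500)),
            _div("wg", ("WestGreenland", "Mainland"), (50, 1500)),
            _div("caa", ("CAA", "Mainland"), (3800, 15000)),
            _admix("lgm_admixture", ("CAA", "Mainland"), (2000, 3500), (0.05, 0.5)),
            _bottleneck("egbm_founder", "EG_BanksMelville", (10, 500)),
            _bottleneck("wg_founder", "WestGreenland", (10, 500)),
        ],
        **common,
    )
    return [s1, s2, s3, s4]


def bsi_like_model_set() -> list[DemographicScenario]:
    """Three-scenario Barents Sea island model set: Svalbard, an ancient
    Franz Josef Land population sampled 502 generations before present,
    Novaya Zemlya, West Russia, and an ancestral East Russian root.
    Priors are illustrative placeholders, not the study's.
    """
    pops = lambda: [  # noqa: E731
        _pop("Svalbard", (200, 10000), 40),
        _pop("FranzJosefLand", (200, 10000), 3, age=502),
        _pop("NovayaZemlya", (500, 20000), 30),
        _pop("WestRussia", (5000, 100000), 40),
        _pop("EastRussia", (5000, 100000), 40),
    ]
    common = dict(mutation=dict(_MUT_CR))

    s1 = DemographicScenario(
        id="bsi1_stepwise",
        populations=pops(),
        events=[
            _div("svalbard", ("Svalbard", "FranzJosefLand"), (520, 1400)),
            _div("fjl", ("FranzJosefLand", "NovayaZemlya"), (620, 1600)),
            _div("nz", ("NovayaZemlya", "WestRussia"), (700, 2800)),
            _div("wr", ("WestRussia", "EastRussia"), (3000, 14000)),
        ],
        order_constraints=[("fjl", "svalbard"), ("nz", "fjl")],
        **common,
    )
    s2 = DemographicScenario(
        id="bsi2_svalbard_early",
        populations=pops(),
        events=[
            _div("svalbard", ("Svalbard", "EastRussia"), (3000, 14000)),
            _div("fjl", ("FranzJosefLand", "NovayaZemlya"), (620, 1600)),
            _div("nz", ("NovayaZemlya", "WestRussia"), (700, 2800)),
            _div("wr", ("WestRussia", "EastRussia"), (3000, 14000)),
        ],
        order_constraints=[("nz", "fjl")],
        **common,
    )
    s3 = DemographicScenario(
        id="bsi3_nz_admixture",
        populations=pops(),
        events=[
            _div("svalbard", ("Svalbard", "FranzJosefLand"), (520, 1400)),
            _div("fjl", ("FranzJosefLand", "NovayaZemlya"), (620, 1600)),
            _div("nz", ("NovayaZemlya", "WestRussia"), (700, 2800)),
            _div("wr", ("WestRussia", "EastRussia"), (3000, 14000)),
            _admix("wr_into_nz", ("NovayaZemlya", "WestRussia"), (100, 600), (0.05, 0.5)),
        ],
        order_constraints=[("fjl", "svalbard"), ("nz", "fjl"), ("fjl", "wr_into_nz")],
        **common,
    )
    return [s1, s2, s3]


def load_example_model_set(name: str) -> list[DemographicScenario]:
    """Load a shipped example model set ('naai' or 'bsi') from package data.

    The files carry illustrative placeholder priors.
    """
    from importlib.resources import files

    doc = json.loads(
        files("postglacial.examples").joinpath(f"{name}_model_set.json").read_text()
    )
    return [DemographicScenario.from_dict(d) for d in doc["scenarios"]]


# --------------------------------------------------------------------------
# synthetic spec
# --------------------------------------------------------------------------


@dataclass
class IceFieldSpec:
    nx: int = 60
    ny: int = 60
    cell_km: float = 30.0
    t_start_ka: float = 24.0
    t_end_ka: float = 0.0
    base: float = 0.45
    trend_per_ka: float = 0.02  # concentration increase per ka of age
    seasonal_amplitude: float = 0.25
    peak_month: int = 3  # March
    gradient_per_km: float = 0.0
    noise_sd: float = 0.0
    land_cols: int = 0  # columns of land strip at the grid's east edge
    lon_0: float = 0.0


@dataclass
class HerdLayoutSpec:
    # population -> (lon, lat) center
    centers: dict = field(default_factory=lambda: {"A": (10.0, 78.0), "B": (20.0, 76.0)})
    herds_per_pop: int = 3
    dispersion_deg: float = 0.5


@dataclass
class SyntheticSpec:
    """Master description of a synthetic study bundle."""

    seed: int = 0
    scenario: DemographicScenario | None = None
    true_values: dict = field(default_factory=dict)  # overrides for the draw
    L: int = 300
    ice: IceFieldSpec = field(default_factory=IceFieldSpec)
    herds: HerdLayoutSpec = field(default_factory=HerdLayoutSpec)


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------


def make_sequence_dataset(spec: SyntheticSpec):
    """Simulate one dataset at the true parameters.

    Returns (alignment, truth) where truth holds the scenario id, the full
    parameter draw actually used, the seed, and L.  Parameters listed in
    ``spec.true_values`` are pinned; the rest are drawn from the priors.
    """
    if spec.scenario is None:
        raise ValueError("spec.scenario is required")
    rng = np.random.default_rng(spec.seed)
    draw = sample_parameters(spec.scenario, rng)
    draw.values.update(spec.true_values)
    aln = coalsim.simulate_dataset(spec.scenario, draw, spec.L, rng)
    # attach coordinates from the herd layout when the populations match
    centers = spec.herds.centers
    if set(aln.populations) <= set(centers):
        lon = np.array([centers[p][0] for p in aln.pop_labels])
        lat = np.array([centers[p][1] for p in aln.pop_labels])
        aln.lon, aln.lat = lon, lat
    truth = {
        "scenario": spec.scenario.id,
        "parameters": dict(draw.values),
        "seed": spec.seed,
        "L": spec.L,
    }
    return aln, truth


def ice_field_closed_form(spec: IceFieldSpec, t_ka, month_index, x_km):
    """Noise-free concentration: base + trend*t + A cos(2π(m - m0)/12) + g·x."""
    seasonal = spec.seasonal_amplitude * np.cos(
        2 * np.pi * (month_index - (spec.peak_month - 1)) / 12.0
    )
    return np.clip(
        spec.base + spec.trend_per_ka * t_ka + seasonal + spec.gradient_per_km * x_km,
        0.0,
        1.0,
    )


def make_ice_field(spec: SyntheticSpec) -> IceField:
    """Gridded monthly ice field with trend + seasonal cycle + gradient + noise."""
    ice = spec.ice
    if ice.nx < 10 or ice.ny < 10:
        raise ValueError("grid must be at least 10 x 10")
    rng = np.random.default_rng(spec.seed + 1)
    times = np.arange(ice.t_start_ka, ice.t_end_ka - 0.5, -1.0)
    xs = (np.arange(ice.nx) - (ice.nx - 1) / 2.0) * ice.cell_km
    ys = (np.arange(ice.ny) - (ice.ny - 1) / 2.0) * ice.cell_km
    months = np.arange(12)
    sic = np.empty((times.size, 12, ice.ny, ice.nx))
    for ti, t in enumerate(times):
        for mi in months:
            clean = ice_field_closed_form(ice, t, mi, xs[None, :])
            grid = np.broadcast_to(clean, (ice.ny, ice.nx)).copy()
            if ice.noise_sd > 0:
                grid += rng.normal(0.0, ice.noise_sd, size=grid.shape)
            sic[ti, mi] = np.clip(grid, 0.0, 1.0)
    land = np.zeros((times.size, ice.ny, ice.nx), dtype=np.int8)
    if ice.land_cols > 0:
        land[:, :, -ice.land_cols:] = 1
    ds = xr.Dataset(
        {
            "sic": (("time_ka", "month", "y", "x"), sic),
            "land_mask": (("time_ka", "y", "x"), land),
        },
        coords={"time_ka": times, "month": MONTHS, "y": ys, "x": xs},
    )
    return IceField(ds, LaeaProjection(lon_0=ice.lon_0))


def make_locations(spec: SyntheticSpec) -> HerdLocations:
    """Herd coordinates scattered around each population center."""
    layout = spec.herds
    rng = np.random.default_rng(spec.seed + 2)
    rows = []
    for pop, (lon, lat) in layout.centers.items():
        for h in range(layout.herds_per_pop):
            rows.append(
                {
                    "herd": f"{pop}_herd{h + 1}",
                    "population": pop,
                    "lon": lon + rng.normal(0.0, layout.dispersion_deg),
                    "lat": lat + rng.normal(0.0, layout.dispersion_deg),
                }
            )
    return HerdLocations(pd.DataFrame(rows))


def write_bundle(spec: SyntheticSpec, outdir) -> dict:
    """Emit a full bundle: FASTA + metadata TSV + herds TSV + NetCDF + truth
    JSON + scenario config.  Returns the paths written."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    aln, truth = make_sequence_dataset(spec)
    paths["fasta"] = out / "sequences.fasta"
    aln.to_fasta(paths["fasta"])
    paths["metadata"] = out / "metadata.tsv"
    aln.metadata_frame().to_csv(paths["metadata"], sep="\t", index=False)
    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2)
    paths["scenario"] = out / "scenario.json"
    spec.scenario.to_json(paths["scenario"])

    herds = make_locations(spec)
    paths["herds"] = out / "herds.tsv"
    herds.to_tsv(paths["herds"])

    field_ = make_ice_field(spec)
    paths["ice"] = out / "ice_field.nc"
    field_.to_netcdf(paths["ice"])

    config = {
        "seed": spec.seed,
        "L": spec.L,
        "ice": asdict(spec.ice),
        "herds": {"centers": spec.herds.centers,
                  "herds_per_pop": spec.herds.herds_per_pop,
                  "dispersion_deg": spec.herds.dispersion_deg},
    }
    paths["config"] = out / "config.json"
    with open(paths["config"], "w") as fh:
        json.dump(config, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
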