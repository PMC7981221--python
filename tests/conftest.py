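"""Shared fixtures: small synthetic bundles and directly simulated model tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from reefgap import classify as _classify
from reefgap import covariates as _cov
from reefgap import io as _io
from reefgap import movements as _mov
from reefgap.simulate import SimConfig, SpeciesSim, simulate


def small_sim_config(**overrides) -> SimConfig:
    """A two-species bundle spanning the wet/dry season boundary."""
    base = dict(
        start="2014-02-15",
        days=45.0,
        n_receivers=12,
        species=(
            SpeciesSim("gray_reef", 10, 0.69, 119.15, 18.07, 0.75, "GR"),
            SpeciesSim("silvertip", 8, 0.73, 123.56, 19.14, 0.59, "ST"),
        ),
    )
    base.update(overrides)
    return SimConfig(**base)


def make_model_table(
    seed: int,
    n_tags: int = 150,
    n_receivers: int = 15,
    per_tag: int = 40,
    beta0: float = -0.5,
    beta_species: float = 0.45,
    beta_night: float = 0.5,
    beta_wet: float = 0.16,
    sigma_tag: float = 0.5,
    sigma_receiver: float = 0.5,
) -> pd.DataFrame:
    """Directly simulated modelling table from the two-intercept logistic model."""
    rng = np.random.default_rng(seed)
    n = n_tags * per_tag
    tag_idx = np.repeat(np.arange(n_tags), per_tag)
    rec_idx = rng.integers(n_receivers, size=n)
    species = np.where(tag_idx % 2 == 0, "gray_reef", "silvertip")
    diel = rng.choice(["day", "night"], size=n)
    season = rng.choice(["dry", "wet"], size=n)
    u_tag = rng.normal(0, sigma_tag, n_tags)
    u_rec = rng.normal(0, sigma_receiver, n_receivers)
    eta = (
        beta0
        + beta_species * (species == "silvertip")
        + beta_night * (diel == "night")
        + beta_wet * (season == "wet")
        + u_tag[tag_idx]
        + u_rec[rec_idx]
    )
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    table = pd.DataFrame(
        {
            "label": y,
            "species": species,
            "sex": rng.choice(["F", "M"], size=n),
            "log_size": rng.normal(4.8, 0.15, n),
            "diel": diel,
            "season": season,
            "tag_id": np.array([f"T{i:03d}" for i in range(n_tags)])[tag_idx],
            "receiver_id": np.array([f"R{i:02d}" for i in range(n_receivers)])[rec_idx],
        }
    )
    table.attrs["u_tag"] = u_tag
    table.attrs["u_receiver"] = u_rec
    return table


@pytest.fixture(scope="session")
def sim_small():
    return simulate(small_sim_config(), seed=7)


@pytest.fixture(scope="session")
def classified_small(sim_small):
    """Extraction + filters + thresholds + labels on the small bundle."""
    sim = sim_small
    species_of = dict(zip(sim.individuals["tag_id"], sim.individuals["species"]))
    det = _io.filter_known_tags(sim.detections, sim.individuals)
    mov = _mov.extract_movements(det)
    mov = _mov.filter_recursions(mov)
    dist = _mov.interreceiver_distances(sim.receivers)
    mov = _mov.compute_rdet(mov, dist, species_of)
    mov = _mov.filter_transitions(mov)
    thresholds = _classify.derive_thresholds(mov, species_of)
    labelled = _classify.classify_movements(mov, thresholds, species_of)
    table = _cov.build_model_table(labelled, sim.individuals)
    return {
        "sim": sim,
        "species_of": species_of,
        "movements": mov,
        "thresholds": thresholds,
        "labelled": labelled,
        "table": table,
    }


@pytest.fixture()
def tiny_detections():
    ts = pd.to_datetime(
        ["2015-06-01T00:00:00Z", "2015-06-01T00:01:40Z", "2015-06-01T00:16:40Z"]
    )
    return pd.DataFrame(
        {"tag_id": ["A", "A", "A"], "receiver_id": ["R1", "R1", "R2"], "timestamp": ts}
    )
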