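"""Packaged reference fixtures: the clemastine-fumarate/ScCO2 dataset
(24 isothermal points, 308-338 K, 12-27 MPa), species property files, and
the published correlation constants used for cross-checks."""

import json
from importlib import resources

from ..core import ComponentSpec, SolubilityDataset

_PKG = resources.files(__name__)


def _read_json(name: str):
    return json.loads((_PKG / name).read_text())


def load_clemastine_dataset() -> SolubilityDataset:
    """The 24-point clemastine fumarate solubility table."""
    with resources.as_file(_PKG / "clemastine_table2.csv") as p:
        return SolubilityDataset.from_csv(p, label="clemastine fumarate / ScCO2")


def load_clemastine() -> ComponentSpec:
    raw = _read_json("clemastine_props.json")
    return ComponentSpec(
        M=raw["M_g_mol"],
        Tc=raw["Tc_K"],
        Pc=raw["Pc_MPa"],
        omega=raw["omega"],
        Vsolid=raw["Vsolid_m3_mol"],
        psub_table={float(k): v for k, v in raw["psub_Pa"].items()},
        name=raw["name"],
    )


def load_co2() -> ComponentSpec:
    raw = _read_json("co2_props.json")
    return ComponentSpec(
        M=raw["M_g_mol"],
        Tc=raw["Tc_K"],
        Pc=raw["Pc_MPa"],
        omega=raw["omega"],
        name=raw["name"],
    )


def load_density_constants() -> dict:
    """Published density-model constant vectors {model_id: {values, aard_percent, r2}}."""
    return _read_json("table4_constants.json")


def load_eos_constants() -> dict:
    """Published PR-EoS/vdW2 interaction and sublimation-form constants."""
    return _read_json("table5_eos.json")


def load_cluster_constants() -> dict:
    """Published cluster-model parameter sets for both variants."""
    return _read_json("table6_cluster.json")


def load_gc_table(name: str) -> dict:
    """Raw group-contribution table JSON by file stem (e.g. 'joback_tc')."""
    return _read_json(f"{name}.json")
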