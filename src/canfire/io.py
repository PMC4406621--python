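"""Serialization: flat JSON configs, protocol files, CSV trace dumps.

Cell parameters and network topologies round-trip through plain JSON with
keys named after the model symbols; simulation results are written as one
CSV per cell (t, V, Ca_i, g_CAN) plus a spike-times CSV, so any plotting
tool can consume them.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cells import InterneuronParams, PyramidalParams
from .engine import SimulationResult
from .kinetics import KineticConstants
from .network import NetworkConfig, SynapseSpec
from .stimulus import StimulusElement

__all__ = [
    "params_to_dict",
    "params_from_dict",
    "network_to_dict",
    "network_from_dict",
    "save_network",
    "load_network",
    "save_protocol",
    "load_protocol",
    "save_result",
]


def params_to_dict(p) -> dict:
    """Flat key/value dict of a cell parameter set (kinetic constants
    inlined with a ``const.`` prefix)."""
    d = {}
    for f in dataclasses.fields(p):
        v = getattr(p, f.name)
        if isinstance(v, KineticConstants):
            for g in dataclasses.fields(v):
                d[f"const.{g.name}"] = getattr(v, g.name)
        else:
            d[f.name] = v
    d["_kind"] = ("pyramidal" if isinstance(p, PyramidalParams)
                  else "interneuron")
    return d


def params_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("_kind")
    const_kw = {k.split(".", 1)[1]: d.pop(k)
                for k in list(d) if k.startswith("const.")}
    cls = PyramidalParams if kind == "pyramidal" else InterneuronParams
    return cls(const=KineticConstants(**const_kw), **d)


def network_to_dict(net: NetworkConfig) -> dict:
    return {
        "pyramidal": [params_to_dict(p) for p in net.pyramidal],
        "interneurons": [params_to_dict(p) for p in net.interneurons],
        "synapses": [dataclasses.asdict(s) for s in net.synapses],
    }


def network_from_dict(d: dict) -> NetworkConfig:
    net = NetworkConfig(
        pyramidal=[params_from_dict(p) for p in d["pyramidal"]],
        interneurons=[params_from_dict(p) for p in d["interneurons"]],
        synapses=[SynapseSpec(**s) for s in d["synapses"]],
    )
    net.validate()
    return net


def save_network(net: NetworkConfig, path) -> None:
    Path(path).write_text(json.dumps(network_to_dict(net), indent=2))


def load_network(path) -> NetworkConfig:
    return network_from_dict(json.loads(Path(path).read_text()))


def save_protocol(protocol, path) -> None:
    Path(path).write_text(
        json.dumps([e.to_dict() for e in protocol], indent=2))


def load_protocol(path) -> list:
    return [StimulusElement.from_dict(d)
            for d in json.loads(Path(path).read_text())]


def save_result(res: SimulationResult, outdir) -> None:
    """One trace CSV per cell plus a spike-times CSV and a metadata JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for c in range(res.n_cells):
        pd.DataFrame({
            "t_ms": res.t, "V_mV": res.V[c], "Ca_uM": res.Ca[c],
            "g_CAN_mS_cm2": res.g_CAN[c],
        }).to_csv(out / f"cell{c}_traces.csv", index=False)
    rows = [(c, t) for c in range(res.n_cells) for t in res.spikes[c]]
    pd.DataFrame(rows, columns=["cell", "spike_time_ms"]).to_csv(
        out / "spikes.csv", index=False)
    (out / "run.json").write_text(json.dumps(
        {"protocol": res.protocol, "meta": res.meta}, indent=2))
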