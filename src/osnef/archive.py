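"""Serialization of trained networks: JSON metadata + numeric blocks.

A trained :class:`~osnef.networks.TaskNetwork` is stored as a single ``.npz``
archive holding every numeric factor (encoder tensors, decoders, fixed
weights, tuning parameters) plus one JSON string describing the structure, so
a network trained once can be reloaded and re-simulated for testing without
retraining.
"""

from __future__ import annotations

import json

import numpy as np

from .encoding import Connection, Decoders, Population
from .networks import TaskNetwork, Wire
from .synapses import FilterParams, SynapseSpec

__all__ = ["save_network", "load_network"]

_POP_ARRAYS = ("encoders", "gain", "bias", "x_intercepts", "max_rates")


def _syn_meta(spec: SynapseSpec) -> dict:
    return {
        "kind": spec.kind,
        "tau_rise": spec.filter.tau_rise,
        "tau_fall": spec.filter.tau_fall,
        "reversal_potential": spec.reversal_potential,
        "target_compartment": spec.target_compartment,
        "mg_concentration": spec.mg_concentration,
    }


def _syn_from_meta(m: dict) -> SynapseSpec:
    return SynapseSpec(
        kind=m["kind"],
        filter=FilterParams(m["tau_rise"], m["tau_fall"]),
        reversal_potential=None if m["kind"] == "current" else m["reversal_potential"],
        target_compartment=m["target_compartment"],
        mg_concentration=m["mg_concentration"],
    )


def save_network(net: TaskNetwork, path: str) -> None:
    """Write a trained network to a single ``.npz`` archive."""
    blocks: dict[str, np.ndarray] = {}
    meta: dict = {
        "topology": net.topology,
        "readout_pop": net.readout_pop,
        "inputs": {k: [v[0], v[1]] for k, v in net.inputs.items()},
        "readout_filter": [net.readout_filter.tau_rise, net.readout_filter.tau_fall],
        "meta": {k: v for k, v in net.meta.items()
                 if isinstance(v, (str, int, float, bool, type(None)))},
        "populations": {},
        "wires": [],
    }
    for name, pop in net.populations.items():
        meta["populations"][name] = {
            "kind": pop.kind, "n": pop.n, "dims": pop.dims,
            "radius": pop.radius, "neuron_options": pop.neuron_options,
        }
        for arr in _POP_ARRAYS:
            blocks[f"pop/{name}/{arr}"] = getattr(pop, arr)
    for i, w in enumerate(net.wires):
        wm = {"source": w.source, "target": w.target, "synapse": _syn_meta(w.synapse),
              "trained": w.connection is not None}
        if w.connection is not None:
            blocks[f"wire/{i}/decoders"] = w.connection.decoders.d
            blocks[f"wire/{i}/encoder_tensor"] = w.connection.encoder_tensor
            wm["function"] = w.connection.function
        else:
            blocks[f"wire/{i}/weights"] = w.weights
        meta["wires"].append(wm)
    blocks["readout/d"] = net.readout.d
    blocks["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **blocks)


def load_network(path: str) -> TaskNetwork:
    """Reload a network saved with :func:`save_network`."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        pops = {}
        for name, pm in meta["populations"].items():
            pops[name] = Population(
                kind=pm["kind"], n=pm["n"], dims=pm["dims"],
                encoders=z[f"pop/{name}/encoders"], gain=z[f"pop/{name}/gain"],
                bias=z[f"pop/{name}/bias"], x_intercepts=z[f"pop/{name}/x_intercepts"],
                max_rates=z[f"pop/{name}/max_rates"],
                neuron_options=pm["neuron_options"], radius=pm["radius"],
            )
        wires = []
        for i, wm in enumerate(meta["wires"]):
            spec = _syn_from_meta(wm["synapse"])
            if wm["trained"]:
                conn = Connection(
                    pre=pops[wm["source"]], post=pops[wm["target"]],
                    decoders=Decoders(d=z[f"wire/{i}/decoders"], function=wm.get("function", "f")),
                    encoder_tensor=z[f"wire/{i}/encoder_tensor"],
                    synapse=spec, function=wm.get("function", "f"),
                )
                wires.append(Wire(wm["source"], wm["target"], spec, connection=conn))
            else:
                wires.append(Wire(wm["source"], wm["target"], spec,
                                  weights=z[f"wire/{i}/weights"]))
        net = TaskNetwork(
            populations=pops,
            wires=wires,
            inputs={k: (v[0], v[1]) for k, v in meta["inputs"].items()},
            readout_pop=meta["readout_pop"],
            readout=Decoders(d=z["readout/d"], function="readout"),
            readout_filter=FilterParams(*meta["readout_filter"]),
            topology=meta["topology"],
            meta=meta["meta"],
        )
    return net
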