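"""Config-file (de)serialization for cascade parameter sets.

Schema (YAML or JSON; keys are stable):

.. code-block:: yaml

    gamma: 0.05                  # shared dilution rate, min^-1
    genes:
      - burst_rate: 12.5         # bursts/min; OR steady_state: 1000
        burst: {family: geometric, mean: 4}
        relative_threshold: 0.55 # OR threshold: 440 (concentration)

Exactly one of ``burst_rate``/``steady_state`` and exactly one of
``threshold``/``relative_threshold`` per gene.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .model import BurstModel, CascadeSpec, GeneSpec

__all__ = ["cascade_from_dict", "cascade_to_dict", "load_cascade", "dump_cascade"]


def cascade_from_dict(data: dict) -> CascadeSpec:
    try:
        gamma = float(data["gamma"])
        gene_entries = data["genes"]
    except KeyError as err:
        raise ValueError(f"config missing required key {err}") from None
    genes = []
    for entry in gene_entries:
        burst = BurstModel(
            family=entry["burst"].get("family", "geometric"),
            mean=float(entry["burst"]["mean"]),
        )
        thr = entry.get("threshold")
        rel = entry.get("relative_threshold")
        if "burst_rate" in entry and "steady_state" in entry:
            raise ValueError("give burst_rate or steady_state, not both")
        if "burst_rate" in entry:
            genes.append(
                GeneSpec(
                    burst_rate=float(entry["burst_rate"]),
                    burst=burst,
                    threshold=thr,
                    relative_threshold=rel,
                )
            )
        elif "steady_state" in entry:
            genes.append(
                GeneSpec.from_steady_state(
                    steady_state=float(entry["steady_state"]),
                    burst=burst,
                    gamma=gamma,
                    threshold=thr,
                    relative_threshold=rel,
                )
            )
        else:
            raise ValueError("each gene needs burst_rate or steady_state")
    return CascadeSpec(genes=tuple(genes), dilution_rate=gamma)


def cascade_to_dict(spec: CascadeSpec) -> dict:
    genes = []
    for g in spec.genes:
        entry: dict = {
            "burst_rate": g.burst_rate,
            "burst": {"family": g.burst.family, "mean": g.burst.mean},
        }
        if g.threshold is not None:
            entry["threshold"] = g.threshold
        else:
            entry["relative_threshold"] = g.relative_threshold
        genes.append(entry)
    return {"gamma": spec.dilution_rate, "genes": genes}


def load_cascade(path) -> CascadeSpec:
    """Read a cascade config from a YAML (or JSON) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not contain a mapping")
    return cascade_from_dict(data)


def dump_cascade(spec: CascadeSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(cascade_to_dict(spec), sort_keys=False))
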