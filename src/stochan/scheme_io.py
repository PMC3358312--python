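"""Serialization of kinetic schemes and run configurations.

Scheme files are YAML or JSON mappings::

    name: my_channel
    states: [c0, c1, o]
    open_state: o
    pairs:
      - from: c0
        to: c1
        forward: {family: linexp, a: 0.1, vh: -40.0, k: 10.0, scale: 2}
        backward: {family: exp, A: 4.0, vh: -65.0, k: -18.0}
      - from: c1
        to: o
        forward: {family: constant, value: 1.5}
        backward: {family: sigmoid, A: 1.0, vh: -35.0, k: 10.0}

``states`` may also be an integer count, in which case pair endpoints
are state indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .kinetics import KineticScheme, SchemeError, TransitionPair
from .rates import ConstantRate, ExpRate, LinExpRate, RateFunction, SigmoidRate

__all__ = [
    "rate_to_dict",
    "rate_from_dict",
    "scheme_to_dict",
    "scheme_from_dict",
    "load_scheme",
    "save_scheme",
]

_FAMILIES = {
    "constant": (ConstantRate, ("value",)),
    "linexp": (LinExpRate, ("a", "vh", "k")),
    "exp": (ExpRate, ("A", "vh", "k")),
    "sigmoid": (SigmoidRate, ("A", "vh", "k")),
}


def rate_to_dict(rate: RateFunction) -> dict:
    try:
        _, fields = _FAMILIES[rate.family]
    except KeyError:
        raise SchemeError(f"rate family {rate.family!r} is not serialisable")
    d = {"family": rate.family}
    d.update({f: getattr(rate, f) for f in fields})
    if rate.scale != 1.0:
        d["scale"] = rate.scale
    return d


def rate_from_dict(d: dict) -> RateFunction:
    d = dict(d)
    family = d.pop("family")
    if family not in _FAMILIES:
        raise SchemeError(
            f"unknown rate family {family!r}; expected one of {sorted(_FAMILIES)}"
        )
    cls, fields = _FAMILIES[family]
    scale = d.pop("scale", 1.0)
    unknown = set(d) - set(fields)
    if unknown:
        raise SchemeError(f"unknown parameters {sorted(unknown)} for family {family!r}")
    return cls(scale=scale, **d)


def scheme_to_dict(scheme: KineticScheme) -> dict:
    names = scheme.state_names or [f"s{i}" for i in range(scheme.n_states)]
    return {
        "name": scheme.name,
        "states": list(names),
        "open_state": names[scheme.open_state],
        "pairs": [
            {
                "from": names[p.i],
                "to": names[p.j],
                "forward": rate_to_dict(p.forward),
                "backward": rate_to_dict(p.backward),
            }
            for p in scheme.pairs
        ],
    }


def scheme_from_dict(d: dict) -> KineticScheme:
    states = d["states"]
    if isinstance(states, int):
        names = [f"s{i}" for i in range(states)]
    else:
        names = [str(s) for s in states]
    index = {n: i for i, n in enumerate(names)}

    def resolve(ref):
        if isinstance(ref, int):
            return ref
        if ref not in index:
            raise SchemeError(f"unknown state {ref!r}")
        return index[ref]

    pairs = [
        TransitionPair(
            i=resolve(p["from"]),
            j=resolve(p["to"]),
            forward=rate_from_dict(p["forward"]),
            backward=rate_from_dict(p["backward"]),
        )
        for p in d["pairs"]
    ]
    return KineticScheme(
        n_states=len(names),
        pairs=pairs,
        open_state=resolve(d["open_state"]),
        name=d.get("name", "scheme"),
        state_names=names,
    )


def load_scheme(path) -> KineticScheme:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scheme file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return scheme_from_dict(data)


def save_scheme(scheme: KineticScheme, path) -> None:
    path = Path(path)
    d = scheme_to_dict(scheme)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
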