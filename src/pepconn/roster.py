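"""Canonical roster of the 302 hermaphrodite *C. elegans* neurons.

The roster fixes node identity and ordering for every adjacency matrix in the
package: neurons are sorted alphabetically by name, and all readers, writers
and network builders index against that order. Each neuron carries its
anatomical class (e.g. ``AVAL`` and ``AVAR`` belong to class ``AVA``) and a
functional type: ``sensory``, ``interneuron``, ``motor`` or ``pharyngeal``.
The 20 pharyngeal neurons (14 classes) form the enteric-like pharyngeal
nervous system and are typed ``pharyngeal`` regardless of their within-pharynx
role. URB is typed sensory and the DB class motor, following the most recent
reconciliation of the classical catalogs.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# (class name, member suffix scheme, functional type)
# suffix schemes: "LR" -> class+L, class+R; "" -> single neuron;
# an int n -> class+1 .. class+n (ventral cord numbering, no zero padding
# except DA9/VA12 style names which are plain integers in the catalogs).
_CLASS_TABLE: list[tuple[str, object, str]] = [
    # --- bilateral sensory pairs ---
    ("ADE", "LR", "sensory"), ("ADF", "LR", "sensory"), ("ADL", "LR", "sensory"),
    ("AFD", "LR", "sensory"), ("ALM", "LR", "sensory"), ("ALN", "LR", "sensory"),
    ("ASE", "LR", "sensory"), ("ASG", "LR", "sensory"), ("ASH", "LR", "sensory"),
    ("ASI", "LR", "sensory"), ("ASJ", "LR", "sensory"), ("ASK", "LR", "sensory"),
    ("AWA", "LR", "sensory"), ("AWB", "LR", "sensory"), ("AWC", "LR", "sensory"),
    ("BAG", "LR", "sensory"), ("CEPD", "LR", "sensory"), ("CEPV", "LR", "sensory"),
    ("FLP", "LR", "sensory"), ("IL2", "LR", "sensory"), ("IL2D", "LR", "sensory"),
    ("IL2V", "LR", "sensory"), ("OLL", "LR", "sensory"), ("OLQD", "LR", "sensory"),
    ("OLQV", "LR", "sensory"), ("PDE", "LR", "sensory"), ("PHA", "LR", "sensory"),
    ("PHB", "LR", "sensory"), ("PHC", "LR", "sensory"), ("PLM", "LR", "sensory"),
    ("PLN", "LR", "sensory"), ("PVD", "LR", "sensory"), ("SDQ", "LR", "sensory"),
    ("URB", "LR", "sensory"), ("URX", "LR", "sensory"), ("URYD", "LR", "sensory"),
    ("URYV", "LR", "sensory"),
    # --- bilateral interneuron pairs ---
    ("ADA", "LR", "interneuron"), ("AIA", "LR", "interneuron"),
    ("AIB", "LR", "interneuron"), ("AIM", "LR", "interneuron"),
    ("AIN", "LR", "interneuron"), ("AIY", "LR", "interneuron"),
    ("AIZ", "LR", "interneuron"), ("AUA", "LR", "interneuron"),
    ("AVA", "LR", "interneuron"), ("AVB", "LR", "interneuron"),
    ("AVD", "LR", "interneuron"), ("AVE", "LR", "interneuron"),
    ("AVF", "LR", "interneuron"), ("AVH", "LR", "interneuron"),
    ("AVJ", "LR", "interneuron"), ("AVK", "LR", "interneuron"),
    ("BDU", "LR", "interneuron"), ("CAN", "LR", "interneuron"),
    ("LUA", "LR", "interneuron"), ("PVC", "LR", "interneuron"),
    ("PVN", "LR", "interneuron"), ("PVP", "LR", "interneuron"),
    ("PVQ", "LR", "interneuron"), ("PVW", "LR", "interneuron"),
    ("RIA", "LR", "interneuron"), ("RIB", "LR", "interneuron"),
    ("RIC", "LR", "interneuron"), ("RIF", "LR", "interneuron"),
    ("RIG", "LR", "interneuron"), ("RIP", "LR", "interneuron"),
    ("SAAD", "LR", "interneuron"), ("SAAV", "LR", "interneuron"),
    ("SIAD", "LR", "interneuron"), ("SIAV", "LR", "interneuron"),
    ("SIBD", "LR", "interneuron"), ("SIBV", "LR", "interneuron"),
    # --- bilateral motor pairs ---
    ("HSN", "LR", "motor"), ("IL1", "LR", "motor"), ("IL1D", "LR", "motor"),
    ("IL1V", "LR", "motor"), ("RIM", "LR", "motor"), ("RIV", "LR", "motor"),
    ("RMD", "LR", "motor"), ("RMDD", "LR", "motor"), ("RMDV", "LR", "motor"),
    ("RME", "LR", "motor"), ("RMF", "LR", "motor"), ("RMG", "LR", "motor"),
    ("RMH", "LR", "motor"), ("SABV", "LR", "motor"), ("SMBD", "LR", "motor"),
    ("SMBV", "LR", "motor"), ("SMDD", "LR", "motor"), ("SMDV", "LR", "motor"),
    ("URAD", "LR", "motor"), ("URAV", "LR", "motor"),
    # --- unpaired somatic neurons ---
    ("ALA", "", "interneuron"), ("AQR", "", "sensory"), ("AVG", "", "interneuron"),
    ("AVL", "", "motor"), ("AVM", "", "sensory"), ("DVA", "", "interneuron"),
    ("DVB", "", "motor"), ("DVC", "", "interneuron"), ("PDA", "", "motor"),
    ("PDB", "", "motor"), ("PQR", "", "sensory"), ("PVM", "", "sensory"),
    ("PVR", "", "interneuron"), ("PVT", "", "interneuron"), ("RID", "", "interneuron"),
    ("RIH", "", "interneuron"), ("RIR", "", "interneuron"), ("RIS", "", "interneuron"),
    ("RMED", "", "motor"), ("RMEV", "", "motor"), ("SABD", "", "motor"),
    # --- ventral cord motor classes ---
    ("AS", 11, "motor"), ("DA", 9, "motor"), ("DB", 7, "motor"),
    ("DD", 6, "motor"), ("VA", 12, "motor"), ("VB", 11, "motor"),
    ("VC", 6, "motor"), ("VD", 13, "motor"),
    # --- pharyngeal nervous system (14 classes, 20 neurons) ---
    ("I1", "LR", "pharyngeal"), ("I2", "LR", "pharyngeal"),
    ("I3", "", "pharyngeal"), ("I4", "", "pharyngeal"),
    ("I5", "", "pharyngeal"), ("I6", "", "pharyngeal"),
    ("M1", "", "pharyngeal"), ("M2", "LR", "pharyngeal"),
    ("M3", "LR", "pharyngeal"), ("M4", "", "pharyngeal"),
    ("M5", "", "pharyngeal"), ("MC", "LR", "pharyngeal"),
    ("MI", "", "pharyngeal"), ("NSM", "LR", "pharyngeal"),
]

NEURON_TYPES = ("sensory", "interneuron", "motor", "pharyngeal")

PHARYNGEAL_CLASSES = frozenset(
    c for c, _, t in _CLASS_TABLE if t == "pharyngeal"
)


@dataclass(frozen=True)
class NeuronRoster:
    """Fixed, ordered roster of neurons with class and type annotations."""

    names: tuple[str, ...]
    class_of: dict[str, str] = field(repr=False)
    type_of: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate neuron names in roster")
        for n in self.names:
            if self.type_of[n] not in NEURON_TYPES:
                raise ValueError(f"unknown neuron type for {n}: {self.type_of[n]}")
        # pharyngeal typing must agree with pharyngeal class membership
        for n in self.names:
            is_ph = self.class_of[n] in PHARYNGEAL_CLASSES
            if is_ph != (self.type_of[n] == "pharyngeal"):
                raise ValueError(f"inconsistent pharyngeal annotation for {n}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.names)}

    def classes(self) -> dict[str, list[str]]:
        """Map each anatomical class to its member neurons (roster order)."""
        out: dict[str, list[str]] = {}
        for n in self.names:
            out.setdefault(self.class_of[n], []).append(n)
        return out

    def is_pharyngeal(self, neuron: str) -> bool:
        return self.class_of[neuron] in PHARYNGEAL_CLASSES


def _expand(cls: str, scheme: object) -> list[str]:
    if scheme == "LR":
        return [cls + "L", cls + "R"]
    if scheme == "":
        return [cls]
    if isinstance(scheme, int):
        return [f"{cls}{k}" for k in range(1, scheme + 1)]
    raise ValueError(f"bad suffix scheme {scheme!r} for class {cls}")


def canonical_roster() -> NeuronRoster:
    """The 302-neuron hermaphrodite roster in alphabetical order."""
    class_of: dict[str, str] = {}
    type_of: dict[str, str] = {}
    for cls, scheme, typ in _CLASS_TABLE:
        for name in _expand(cls, scheme):
            if name in class_of:
                raise AssertionError(f"duplicate neuron {name} in class table")
            class_of[name] = cls
            type_of[name] = typ
    names = tuple(sorted(class_of))
    if len(names) != 302:
        raise AssertionError(f"roster has {len(names)} neurons, expected 302")
    return NeuronRoster(names=names, class_of=class_of, type_of=type_of)
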