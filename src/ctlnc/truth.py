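"""Planted ground truth emitted alongside every synthetic cohort."""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ConsistencyError


@dataclass
class SyntheticTruth:
    """What was planted: TS/CT/EECT membership, modules, elements, couplings.

    ``activated_samples`` is filled in by the tumor-cohort generator and maps
    each planted CT gene to the set of sample ids in which it was activated.
    """

    ts_genes: set[str] = field(default_factory=set)
    ct_genes: set[str] = field(default_factory=set)
    eect_genes: set[str] = field(default_factory=set)
    module_assignment: dict[str, str] = field(default_factory=dict)
    element_placements: dict[str, str] = field(default_factory=dict)
    methylation_effect: dict[str, int] = field(default_factory=dict)
    exclusive_pairs: list[tuple[str, str]] = field(default_factory=list)
    activated_samples: dict[str, set[str]] = field(default_factory=dict)

    def validate(self, known_genes: set[str] | None = None) -> None:
        if not self.eect_genes <= self.ct_genes:
            raise ConsistencyError("eect_genes must be a subset of ct_genes")
        if not self.ct_genes <= self.ts_genes:
            raise ConsistencyError("ct_genes must be a subset of ts_genes")
        if known_genes is not None:
            for elem, target in self.element_placements.items():
                if target != "background" and target not in known_genes:
                    raise ConsistencyError(f"element {elem!r} targets unknown gene {target!r}")

    def to_dict(self) -> dict:
        return {
            "ts_genes": sorted(self.ts_genes),
            "ct_genes": sorted(self.ct_genes),
            "eect_genes": sorted(self.eect_genes),
            "module_assignment": dict(sorted(self.module_assignment.items())),
            "element_placements": dict(sorted(self.element_placements.items())),
            "methylation_effect": dict(sorted(self.methylation_effect.items())),
            "exclusive_pairs": [list(p) for p in self.exclusive_pairs],
            "activated_samples": {g: sorted(s) for g, s in sorted(self.activated_samples.items())},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticTruth":
        return cls(
            ts_genes=set(data["ts_genes"]),
            ct_genes=set(data["ct_genes"]),
            eect_genes=set(data["eect_genes"]),
            module_assignment=dict(data["module_assignment"]),
            element_placements=dict(data["element_placements"]),
            methylation_effect={k: int(v) for k, v in data["methylation_effect"].items()},
            exclusive_pairs=[tuple(p) for p in data["exclusive_pairs"]],
            activated_samples={g: set(s) for g, s in data.get("activated_samples", {}).items()},
        )
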