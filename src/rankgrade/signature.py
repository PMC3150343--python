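"""Directional grade signatures.

A grade signature is two disjoint sets of probe identifiers: probes whose
expression is increased in high-grade (G3) tumours and probes increased in
low-grade (G1) tumours.  The classifier in :mod:`rankgrade.grading` compares
the within-profile mean ranks of the two sets, so the signature is the only
piece of prior knowledge the method uses.

Signatures are stored either as a two-column TSV (``probe_id<TAB>direction``
with direction ``G3up`` or ``G1up``) or as a JSON object with ``g3_up`` and
``g1_up`` arrays.  Probe identifiers are opaque strings (Affymetrix probe-set
IDs in the shipped fixtures); no gene-symbol mapping is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "GradeSignature",
    "SignatureDiff",
    "CoverageReport",
    "load_signature",
    "save_signature",
    "restrict_to_platform",
    "diff_signatures",
    "bundled_signature",
    "BUNDLED_SIGNATURES",
]

_DIRECTIONS = {"G3up", "G1up"}


@dataclass(frozen=True)
class GradeSignature:
    """Two disjoint directional probe-identifier sets.

    Parameters
    ----------
    name
        Short label used in logs and reports.
    g3_up
        Probes with increased expression in high-grade (G3) tumours.
    g1_up
        Probes with increased expression in low-grade (G1) tumours.
    """

    name: str
    g3_up: frozenset[str]
    g1_up: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "g3_up", frozenset(self.g3_up))
        object.__setattr__(self, "g1_up", frozenset(self.g1_up))
        if not self.g3_up or not self.g1_up:
            raise ValueError(
                f"signature {self.name!r}: both directional sets must be non-empty"
            )
        overlap = self.g3_up & self.g1_up
        if overlap:
            raise ValueError(
                f"signature {self.name!r}: probes in both sets: {sorted(overlap)}"
            )

    def __len__(self) -> int:
        return len(self.g3_up) + len(self.g1_up)

    @property
    def probes(self) -> frozenset[str]:
        """All probe identifiers in the signature."""
        return self.g3_up | self.g1_up


@dataclass(frozen=True)
class SignatureDiff:
    """Set difference between an original and a revised signature."""

    removed_from_g3: frozenset[str]
    removed_from_g1: frozenset[str]
    added: frozenset[str]

    @property
    def is_empty(self) -> bool:
        return not (self.removed_from_g3 or self.removed_from_g1 or self.added)


@dataclass(frozen=True)
class CoverageReport:
    """Per-set platform coverage after restriction."""

    retained_g3: int
    total_g3: int
    retained_g1: int
    total_g1: int

    @property
    def coverage_g3(self) -> float:
        return self.retained_g3 / self.total_g3

    @property
    def coverage_g1(self) -> float:
        return self.retained_g1 / self.total_g1


def _parse_records(records: list[tuple[str, str]], name: str) -> GradeSignature:
    g3: set[str] = set()
    g1: set[str] = set()
    for probe, direction in records:
        if direction not in _DIRECTIONS:
            raise ValueError(
                f"unknown direction label {direction!r} for probe {probe!r} "
                f"(expected one of {sorted(_DIRECTIONS)})"
            )
        target = g3 if direction == "G3up" else g1
        other = g1 if direction == "G3up" else g3
        if probe in other:
            raise ValueError(
                f"probe {probe!r} listed with conflicting directions"
            )
        target.add(probe)
    return GradeSignature(name=name, g3_up=frozenset(g3), g1_up=frozenset(g1))


def load_signature(path: str | Path, format: str | None = None) -> GradeSignature:
    """Load a signature from TSV or JSON.

    ``format`` is ``"tsv"`` or ``"json"``; if omitted it is inferred from the
    file extension.  Record order never affects the result.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown signature format {format!r}")
    text = path.read_text()
    name = path.stem
    if format == "json":
        obj = json.loads(text)
        records = [(p, "G3up") for p in obj["g3_up"]]
        records += [(p, "G1up") for p in obj["g1_up"]]
        if len(set(obj["g3_up"])) != len(obj["g3_up"]) or len(
            set(obj["g1_up"])
        ) != len(obj["g1_up"]):
            raise ValueError(f"duplicate probe identifiers in {path}")
        return _parse_records(records, obj.get("name", name))
    records = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for i, line in enumerate(lines):
        fields = line.rstrip("\r\n").split("\t")
        if i == 0 and fields[:2] == ["probe_id", "direction"]:
            continue
        if len(fields) < 2:
            raise ValueError(f"{path}: line {i + 1}: expected 2 tab-separated fields")
        records.append((fields[0], fields[1]))
    seen: dict[str, str] = {}
    for probe, direction in records:
        if probe in seen and seen[probe] == direction:
            raise ValueError(f"duplicate probe identifier {probe!r} in {path}")
        seen.setdefault(probe, direction)
    return _parse_records(records, name)


def save_signature(sig: GradeSignature, path: str | Path, format: str | None = None) -> None:
    """Write a signature as TSV or JSON (the formats `load_signature` reads)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format == "json":
        obj = {
            "name": sig.name,
            "g3_up": sorted(sig.g3_up),
            "g1_up": sorted(sig.g1_up),
        }
        path.write_text(json.dumps(obj, indent=2) + "\n")
    elif format == "tsv":
        lines = ["probe_id\tdirection"]
        lines += [f"{p}\tG3up" for p in sorted(sig.g3_up)]
        lines += [f"{p}\tG1up" for p in sorted(sig.g1_up)]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown signature format {format!r}")


def restrict_to_platform(
    sig: GradeSignature,
    universe: set[str] | frozenset[str],
    min_coverage: float = 0.5,
) -> tuple[GradeSignature, CoverageReport]:
    """Intersect a signature with the probes present on a platform.

    Classification is only defined for probes that were actually measured.
    If either directional set retains less than ``min_coverage`` of its
    probes the call would be unreliable and a ``ValueError`` is raised.
    """
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    universe = frozenset(universe)
    g3 = sig.g3_up & universe
    g1 = sig.g1_up & universe
    report = CoverageReport(
        retained_g3=len(g3),
        total_g3=len(sig.g3_up),
        retained_g1=len(g1),
        total_g1=len(sig.g1_up),
    )
    for label, cov in (("g3_up", report.coverage_g3), ("g1_up", report.coverage_g1)):
        if cov < min_coverage:
            raise ValueError(
                f"signature {sig.name!r}: platform coverage of {label} is "
                f"{cov:.2f} < min_coverage {min_coverage:.2f}"
            )
    return GradeSignature(name=sig.name, g3_up=g3, g1_up=g1), report


def diff_signatures(original: GradeSignature, revised: GradeSignature) -> SignatureDiff:
    """Probes removed from each set, and probes newly added, going original → revised."""
    return SignatureDiff(
        removed_from_g3=original.g3_up - revised.g3_up,
        removed_from_g1=original.g1_up - revised.g1_up,
        added=revised.probes - original.probes,
    )


#: Names of signature fixtures shipped with the package.  The "original" and
#: "optimized" fixtures are synthetic stand-ins that reproduce the published
#: set structure (112 G3-up + 16 G1-up probes; 91 probes after removing 37
#: from the G3 set); see the data README for provenance.
BUNDLED_SIGNATURES = (
    "original_signature_synthetic",
    "optimized_signature_synthetic",
    "toy_signature",
)


def bundled_signature(name: str) -> GradeSignature:
    """Load a packaged signature fixture by name (see ``BUNDLED_SIGNATURES``)."""
    if name not in BUNDLED_SIGNATURES:
        raise KeyError(f"unknown bundled signature {name!r}; choices: {BUNDLED_SIGNATURES}")
    ref = resources.files("rankgrade").joinpath(f"data/{name}.tsv")
    with resources.as_file(ref) as p:
        return load_signature(p, format="tsv")
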