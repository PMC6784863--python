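"""Variety-group and subpopulation nomenclature for Asian cultivated rice.

Nine admixture-defined subpopulations nest inside four major variety groups:
Xian/Indica (XI: XI-1A, XI-1B, XI-2, XI-3), Geng/Japonica (GJ: GJ-tmp,
GJ-sbtrp, GJ-trp), circum-Aus (cA) and circum-Basmati (cB).  Samples that do
not reach the membership threshold for any single subpopulation but do for a
major group are XI-adm / GJ-adm; the rest are fully admixed (admix).
"""

from __future__ import annotations

from dataclasses import dataclass

XI_SUBPOPS = ("XI-1A", "XI-1B", "XI-2", "XI-3")
GJ_SUBPOPS = ("GJ-tmp", "GJ-sbtrp", "GJ-trp")
SUBPOPULATIONS = XI_SUBPOPS + GJ_SUBPOPS + ("cA", "cB")
MAJOR_GROUPS = ("XI", "GJ", "cA", "cB")
ADMIXED_LABELS = ("XI-adm", "GJ-adm", "admix")
ALL_LABELS = SUBPOPULATIONS + ADMIXED_LABELS

MAJOR_GROUP_OF = {
    **{s: "XI" for s in XI_SUBPOPS},
    **{s: "GJ" for s in GJ_SUBPOPS},
    "cA": "cA",
    "cB": "cB",
    "XI-adm": "XI",
    "GJ-adm": "GJ",
    "admix": None,
}


@dataclass
class SubpopAssignment:
    """Per-sample subpopulation label plus the derived major-group mapping."""

    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels differ in length")
        unknown = set(self.labels) - set(ALL_LABELS)
        if unknown:
            raise ValueError(f"unknown subpopulation labels: {sorted(unknown)}")

    def label_of(self, sample: str) -> str:
        return self.labels[self.sample_ids.index(sample)]

    def major_group(self, sample: str) -> str | None:
        return MAJOR_GROUP_OF[self.label_of(sample)]

    def samples_in(self, label: str) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == label]

    def samples_in_major_group(self, group: str) -> list[str]:
        return [
            s
            for s, l in zip(self.sample_ids, self.labels)
            if MAJOR_GROUP_OF[l] == group
        ]

    def core_subpop_samples(self) -> dict[str, list[str]]:
        """Samples per named subpopulation, excluding adm / admix classes."""
        return {sp: self.samples_in(sp) for sp in SUBPOPULATIONS}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tsubpopulation\tmajor_group\n")
            for s, l in zip(self.sample_ids, self.labels):
                fh.write(f"{s}\t{l}\t{MAJOR_GROUP_OF[l] or 'admix'}\n")

    @classmethod
    def from_tsv(cls, path) -> "SubpopAssignment":
        samples, labels = [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("sample"):
                raise ValueError("expected header line starting with 'sample'")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                samples.append(parts[0])
                labels.append(parts[1])
        return cls(samples, labels)
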