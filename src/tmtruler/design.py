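"""TMT channel design: the ordered mapping of reporter channels to samples.

Each multiplexed TMT run carries one sample per reporter channel.  A
:class:`ChannelDesign` records, in channel order, which cell population and
biological replicate each channel holds, and derives the sample labels used
as column names throughout the pipeline (``<population>_<replicate>``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["Channel", "ChannelDesign"]


@dataclass(frozen=True)
class Channel:
    """One TMT reporter channel: label (e.g. ``"1"`` or ``"126"``),
    population id and replicate id."""

    label: str
    population: str
    replicate: str

    @property
    def sample(self) -> str:
        return f"{self.population}_{self.replicate}"


@dataclass
class ChannelDesign:
    channels: list[Channel] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        pairs = [(c.population, c.replicate) for c in self.channels]
        if len(set(pairs)) != len(pairs):
            raise ValueError("(population, replicate) pairs must be unique")
        if not all(c.population for c in self.channels):
            raise ValueError("every channel needs a population id")

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def populations(self) -> list[str]:
        """Population ids in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.channels:
            seen.setdefault(c.population, None)
        return list(seen)

    @property
    def samples(self) -> list[str]:
        return [c.sample for c in self.channels]

    def samples_for(self, population: str) -> list[str]:
        if population not in self.populations:
            raise KeyError(f"unknown population: {population!r}")
        return [c.sample for c in self.channels if c.population == population]

    def replicate_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.channels:
            counts[c.population] = counts.get(c.population, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel_label": [c.label for c in self.channels],
                "population": [c.population for c in self.channels],
                "replicate": [c.replicate for c in self.channels],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ChannelDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"channel_label", "population", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"channel design missing column(s): {sorted(missing)}")
        return cls(
            [
                Channel(row.channel_label, row.population, row.replicate)
                for row in df.itertuples()
            ]
        )

    def drop_samples(self, samples) -> "ChannelDesign":
        """Return a design without the given sample labels (used after QC)."""
        drop = set(samples)
        return ChannelDesign([c for c in self.channels if c.sample not in drop])
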