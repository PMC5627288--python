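"""Experimental design: mapping TMT channels to tissues, groups and subjects.

The study layout is four 10-plex experiments — two per tissue (retina,
vitreous), each carrying 5 control and 5 glaucoma subjects — so that the
20 biological replicates of a tissue span two plexes.
"""
from __future__ import annotations

from dataclasses import dataclass

from .channels import TMT10_CHANNEL_NAMES

GROUP_CONTROL = "control"
GROUP_GLAUCOMA = "glaucoma"
GROUPS = (GROUP_CONTROL, GROUP_GLAUCOMA)


@dataclass(frozen=True)
class ChannelAssignment:
    channel: str
    group: str
    subject: str


@dataclass(frozen=True)
class Plex:
    """One 10-plex experiment: a tissue and ten channel -> sample slots."""

    tissue: str
    plex_id: str
    channels: tuple[ChannelAssignment, ...]

    def __post_init__(self):
        if len(self.channels) != 10:
            raise ValueError(f"plex {self.plex_id}: expected 10 channels, got {len(self.channels)}")
        names = tuple(c.channel for c in self.channels)
        if names != TMT10_CHANNEL_NAMES:
            raise ValueError(f"plex {self.plex_id}: channels must be {TMT10_CHANNEL_NAMES} in order")
        for c in self.channels:
            if c.group not in GROUPS:
                raise ValueError(f"unknown group {c.group!r}")
        n_control = sum(c.group == GROUP_CONTROL for c in self.channels)
        if n_control != 5:
            raise ValueError(
                f"plex {self.plex_id}: design requires 5 control + 5 glaucoma channels, "
                f"got {n_control} control"
            )

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(c.subject for c in self.channels)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(c.group for c in self.channels)


@dataclass(frozen=True)
class PlexDesign:
    """The full multi-plex layout."""

    plexes: tuple[Plex, ...]

    def __post_init__(self):
        seen_ids = set()
        for p in self.plexes:
            if p.plex_id in seen_ids:
                raise ValueError(f"duplicate plex id {p.plex_id!r}")
            seen_ids.add(p.plex_id)
        for tissue in self.tissues:
            subs = [c.subject for p in self.plexes if p.tissue == tissue for c in p.channels]
            if len(subs) != len(set(subs)):
                raise ValueError(f"subject ids must be unique within tissue {tissue!r}")

    @property
    def tissues(self) -> tuple[str, ...]:
        out: list[str] = []
        for p in self.plexes:
            if p.tissue not in out:
                out.append(p.tissue)
        return tuple(out)

    def plexes_for(self, tissue: str) -> tuple[Plex, ...]:
        return tuple(p for p in self.plexes if p.tissue == tissue)

    def samples(self, tissue: str | None = None) -> list[ChannelAssignment]:
        """Channel assignments in plex order, optionally restricted to a tissue."""
        return [
            c
            for p in self.plexes
            if tissue is None or p.tissue == tissue
            for c in p.channels
        ]


def make_plex(tissue: str, plex_id: str, control_subjects: list[str], glaucoma_subjects: list[str]) -> Plex:
    """Lay out 5 control subjects on channels 126-128C and 5 glaucoma on 129N-131."""
    if len(control_subjects) != 5 or len(glaucoma_subjects) != 5:
        raise ValueError("a plex holds exactly 5 control and 5 glaucoma subjects")
    assignments = []
    for i, ch in enumerate(TMT10_CHANNEL_NAMES):
        if i < 5:
            assignments.append(ChannelAssignment(ch, GROUP_CONTROL, control_subjects[i]))
        else:
            assignments.append(ChannelAssignment(ch, GROUP_GLAUCOMA, glaucoma_subjects[i - 5]))
    return Plex(tissue, plex_id, tuple(assignments))


def default_design(tissues: tuple[str, ...] = ("retina", "vitreous")) -> PlexDesign:
    """The study layout: 2 plexes per tissue, 5+5 subjects per plex."""
    plexes = []
    for tissue in tissues:
        t = tissue[:3].upper()
        for k in (1, 2):
            lo = 5 * (k - 1) + 1
            ctrl = [f"{t}_C{j}" for j in range(lo, lo + 5)]
            glau = [f"{t}_G{j}" for j in range(lo, lo + 5)]
            plexes.append(make_plex(tissue, f"{tissue}_plex{k}", ctrl, glau))
    return PlexDesign(tuple(plexes))
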