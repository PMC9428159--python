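"""Experimental design: treatments x replicates in a completely randomized layout."""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_TREATMENTS = ("CK", "MF", "MOF", "OFP", "MSP")


@dataclass(frozen=True)
class StudyDesign:
    """A fertilization trial layout.

    Parameters
    ----------
    treatments : ordered unique treatment labels. Defaults to the five
        fertilization regimes CK (unfertilized control), MF (mineral
        fertilizer), MOF (mineral + commercial organic fertilizer),
        OFP (commercial organic fertilizer) and MSP (maize straw).
    replicates : number of field replicates per treatment (plots).
    seed : base seed propagated to generators built on this design.
    """

    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.treatments) == 0:
            raise ValueError("design needs at least one treatment")
        if len(set(self.treatments)) != len(self.treatments):
            raise ValueError("treatment labels must be unique")
        if self.replicates < 1:
            raise ValueError("replicates_per_treatment must be a positive integer")

    @property
    def n_samples(self) -> int:
        return len(self.treatments) * self.replicates

    def sample_ids(self) -> list[str]:
        return [f"{t}-{r}" for t in self.treatments for r in range(1, self.replicates + 1)]

    def treatment_of(self) -> dict[str, str]:
        """Map each sample id to its treatment label."""
        return {f"{t}-{r}": t for t in self.treatments for r in range(1, self.replicates + 1)}
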