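"""Study-like synthetic datasets with known ground truth.

The generator reproduces the sampling design of a small two-population
resequencing study — 10 unlinked non-coding autosomal loci of 2 kb each
(~20 kb total), 22 chromosomes from population 1 (11 diploid individuals)
and 20 from population 2 (10 individuals), a 25-year generation time and a
1.47e-6 / year whole-locus geometric-mean mutation rate — and simulates it
under the IM model at chosen parameters, recording everything needed to
regenerate the dataset bit-exactly.

The ``table1-like`` preset places the truth in the regime the pipeline is
built for: a large founding fraction (s = 0.96), a recent split
(t = 193 years), a small ancestral size (N_A = 5475) and a strongly
asymmetric present-day size ratio, with migration off.  In that regime
population 2's variation is typically a near-subset of population 1's.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .data_model import MultilocusDataset, StudyDesign
from .simulate import IMParams, simulate_dataset

__all__ = ["paper_like_design", "table1_like_params", "generate_study", "TruthRecord"]


def paper_like_design(n_loci: int = 10, locus_length: int = 2000,
                      n_chrom_pop1: int = 22, n_chrom_pop2: int = 20,
                      mu_per_year: float = 1.47e-6,
                      generation_time: float = 25.0) -> StudyDesign:
    """The default study design (see module docstring)."""
    return StudyDesign(
        n_loci=n_loci,
        locus_lengths=(locus_length,) * n_loci,
        mu_per_locus=(mu_per_year,) * n_loci,
        n_chrom_pop1=n_chrom_pop1,
        n_chrom_pop2=n_chrom_pop2,
        generation_time=generation_time,
    )


def table1_like_params() -> IMParams:
    """Preset truth: N_A = 5475, s = 0.96, t = 193 years, N2 = 681,
    migration off; N1 set mid-range (its posterior is typically flat for
    designs this small)."""
    return IMParams(N_A=5475.0, N1=17000.0, N2=681.0, s=0.96, t_years=193.0,
                    m1=0.0, m2=0.0)


@dataclasses.dataclass(frozen=True)
class TruthRecord:
    """Everything needed to regenerate a synthetic study bit-exactly."""

    params: IMParams
    design: StudyDesign
    root_seed: int
    expected_signatures: tuple = (
        "population 2 diversity typically a near-subset of population 1",
        "few or no private population-2 sites for large s and recent t",
    )

    def to_dict(self) -> dict:
        return {
            "params": dataclasses.asdict(self.params),
            "design": self.design.to_dict(),
            "root_seed": self.root_seed,
            "expected_signatures": list(self.expected_signatures),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def generate_study(params: IMParams | str = "table1-like", seed: int = 0,
                   design: StudyDesign | None = None):
    """Simulate a study-like dataset with recorded truth.

    ``params`` may be an :class:`IMParams` or the string ``"table1-like"``.
    Returns ``(MultilocusDataset, TruthRecord)``; the same (params, design,
    seed) triple always regenerates the identical dataset.
    """
    if isinstance(params, str):
        if params != "table1-like":
            raise ValueError(f"unknown preset {params!r}")
        params = table1_like_params()
    if design is None:
        design = paper_like_design()
    dataset = simulate_dataset(params, design, seed)
    return dataset, TruthRecord(params=params, design=design, root_seed=int(seed))
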