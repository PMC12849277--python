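"""Instrument selection for molecular (protein) traits.

An MR analysis of a protein's effect on the outcome is only trusted when the
protein has enough independent, strongly associated instruments, at least one
of them cis to the encoding gene (a variant acting near its own gene is less
likely to affect the protein through a confounded pathway).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import gwas_io


@dataclass
class GeneLocus:
    protein: str
    chrom: str
    start: int
    end: int


@dataclass
class ProteinInstrumentSet:
    """Selected instruments for one protein, with eligibility bookkeeping."""

    protein: str
    locus: GeneLocus | None
    instruments: pd.DataFrame          # canonical-dialect rows + 'cis' flag
    min_total: int = 3
    min_cis: int = 1
    log: list[str] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.instruments)

    @property
    def n_cis(self) -> int:
        return int(self.instruments["cis"].sum()) if self.n_total else 0

    @property
    def eligible(self) -> bool:
        return (
            self.locus is not None
            and self.n_total >= self.min_total
            and self.n_cis >= self.min_cis
        )


def read_locus_table(path, sep: str = "\t") -> dict[str, GeneLocus]:
    """Read a delimited (protein, chrom, start, end) locus table."""
    df = pd.read_csv(path, sep=sep, dtype={"protein": str, "chrom": str})
    return {
        str(r["protein"]): GeneLocus(str(r["protein"]), str(r["chrom"]),
                                     int(r["start"]), int(r["end"]))
        for _, r in df.iterrows()
    }


def select_instruments(
    assocs: pd.DataFrame,
    protein: str,
    locus: GeneLocus | None,
    ld: gwas_io.LdMatrix | None = None,
    p_threshold: float = 1.7e-11,
    cis_window_kb: float = 1000,
    window_kb: float = 500,
    r2_threshold: float = 0.001,
    min_total: int = 3,
    min_cis: int = 1,
) -> ProteinInstrumentSet:
    """Select independent, strongly associated instruments for one protein.

    Associations below ``p_threshold`` are clumped (same greedy rule as the
    exposure instruments); each retained variant is cis iff it lies on the
    locus chromosome within ``cis_window_kb`` kb of the gene interval.  The
    set is eligible when it has at least ``min_total`` instruments of which
    at least ``min_cis`` are cis.
    """
    log: list[str] = []
    retained = gwas_io.clump(
        assocs, ld=ld, window_kb=window_kb,
        r2_threshold=r2_threshold, p_threshold=p_threshold,
    )
    inst = assocs[assocs["rsid"].isin(retained)].copy().reset_index(drop=True)
    if locus is None:
        log.append(f"{protein}: unknown gene locus; marked ineligible")
        inst["cis"] = False
    else:
        w = cis_window_kb * 1000.0
        inst["cis"] = (
            (inst["chr"].astype(str) == locus.chrom)
            & (inst["pos"] >= locus.start - w)
            & (inst["pos"] <= locus.end + w)
        )
    return ProteinInstrumentSet(
        protein=protein, locus=locus, instruments=inst,
        min_total=min_total, min_cis=min_cis, log=log,
    )
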