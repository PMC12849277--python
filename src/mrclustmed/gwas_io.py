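"""Reading, harmonisation, clumping and Steiger filtering of GWAS summary statistics.

Summary statistics travel as :class:`pandas.DataFrame` objects in a canonical
dialect with columns ``rsid, chr, pos, ea, oa, eaf, beta, se, p, n`` (effect
allele ``ea``, other allele ``oa``, effect-allele frequency ``eaf``).  All
betas are per effect-allele copy, in trait SD units for quantitative traits or
log odds ratios for binary ones.  Every filtering operation returns, next to
its retained rows, an exclusion log — a DataFrame with columns ``rsid`` and
``reason`` — so an analysis can account for every variant it discards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CANONICAL_COLUMNS = ["rsid", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]
#: columns that must be present and valid for a record to be kept
_MANDATORY = ["rsid", "chr", "pos", "ea", "oa", "beta", "se", "p", "n"]

_NUCLEOTIDES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PAIR_COLUMNS = [
    "rsid", "chr", "pos", "ea", "oa",
    "beta_exp", "se_exp", "eaf_exp", "n_exp",
    "beta_out", "se_out", "eaf_out", "n_out",
    "palindromic", "flipped",
]


class SummaryStatsError(ValueError):
    """Raised for malformed summary-statistics inputs (e.g. missing columns)."""


def _exclusion_log(entries: list[tuple[str, str]]) -> pd.DataFrame:
    return pd.DataFrame(entries, columns=["rsid", "reason"])


def read_summary_stats(
    path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a delimited summary-statistics file into the canonical dialect.

    Parameters
    ----------
    path
        Delimited text file with a header row.  Tab- or whitespace-delimited
        by default; pass ``sep`` for anything else.
    column_map
        Mapping from canonical name (``rsid``, ``chr``, ... ``n``) to the
        column header used in the file.  Unmapped canonical names are assumed
        to appear verbatim.

    Returns
    -------
    (stats, exclusions)
        ``stats`` holds the validated records in canonical columns;
        ``exclusions`` logs every dropped row with a reason tag.  Rows failing
        an invariant (non-biallelic alleles, non-positive SE, p outside
        (0, 1], n <= 0) are dropped and counted; rsids occurring more than
        once are dropped entirely (all copies) and tagged ``duplicate``.

    Raises
    ------
    SummaryStatsError
        If a mandatory column is missing from the file.
    """
    raw = pd.read_csv(path, sep=sep if sep is not None else r"\s+", dtype=str)
    column_map = dict(column_map or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        source = column_map.get(canon, canon)
        if source in raw.columns:
            rename[source] = canon
        elif canon in _MANDATORY:
            raise SummaryStatsError(f"missing mandatory column {source!r} (for {canon!r})")
    df = raw.rename(columns=rename)
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    df = df[CANONICAL_COLUMNS].copy()

    for col in ("pos", "eaf", "beta", "se", "p", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["ea"] = df["ea"].astype(str).str.upper()
    df["oa"] = df["oa"].astype(str).str.upper()
    df["chr"] = df["chr"].astype(str)

    excluded: list[tuple[str, str]] = []
    keep = np.ones(len(df), dtype=bool)

    def drop(mask: np.ndarray, reason: str) -> None:
        nonlocal keep
        mask = mask & keep
        for rsid in df.loc[mask, "rsid"]:
            excluded.append((str(rsid), reason))
        keep &= ~mask

    biallelic = df["ea"].isin(_NUCLEOTIDES) & df["oa"].isin(_NUCLEOTIDES)
    drop((~biallelic | (df["ea"] == df["oa"])).to_numpy(), "non-biallelic")
    numeric_ok = (
        df["pos"].notna() & df["beta"].notna() & df["se"].notna()
        & df["p"].notna() & df["n"].notna()
    )
    drop(~numeric_ok.to_numpy(), "unparseable")
    drop((df["se"] <= 0).fillna(False).to_numpy(), "non-positive-se")
    drop(((df["p"] <= 0) | (df["p"] > 1)).fillna(False).to_numpy(), "p-out-of-range")
    drop((df["n"] <= 0).fillna(False).to_numpy(), "n-non-positive")
    bad_eaf = df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1))
    drop(bad_eaf.to_numpy(), "eaf-out-of-range")

    dup = df["rsid"].duplicated(keep=False).to_numpy()
    drop(dup, "duplicate")

    out = df.loc[keep].reset_index(drop=True)
    _warn_p_z_inconsistency(out)
    return out, _exclusion_log(excluded)


def _warn_p_z_inconsistency(df: pd.DataFrame, tol_log10: float = 2.0) -> None:
    # warn (not drop) when the reported p disagrees with the normal p of beta/se
    # by more than `tol_log10` orders of magnitude
    if df.empty:
        return
    with np.errstate(divide="ignore"):
        z = np.abs(df["beta"] / df["se"])
        p_normal = 2.0 * stats.norm.sf(z)
        p_normal = np.clip(p_normal, 1e-300, 1.0)
        gap = np.abs(np.log10(df["p"].clip(lower=1e-300)) - np.log10(p_normal))
    bad = df.loc[gap > tol_log10, "rsid"].tolist()
    if bad:
        warnings.warn(
            f"{len(bad)} record(s) with p inconsistent with beta/se by > {tol_log10} "
            f"orders of magnitude (e.g. {bad[:5]})",
            stacklevel=3,
        )


def write_summary_stats(df: pd.DataFrame, path) -> None:
    """Write summary statistics in the canonical tab-delimited dialect."""
    df[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class LdMatrix:
    """Symmetric matrix of pairwise r-squared values over an ordered rsid list."""

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.rsids)
        if self.r2.shape != (n, n):
            raise ValueError("r2 matrix shape does not match rsid list")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {rsid: i for i, rsid in enumerate(self.rsids)}

    def lookup(self, a: str, b: str) -> float:
        """Pairwise r² between two rsids; 0.0 when either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    @classmethod
    def read(cls, path, sep: str = "\t") -> "LdMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))

    def write(self, path, sep: str = "\t") -> None:
        pd.DataFrame(self.r2, index=self.rsids, columns=self.rsids).to_csv(path, sep=sep)

    @classmethod
    def identity(cls, rsids) -> "LdMatrix":
        rsids = list(rsids)
        return cls(rsids, np.eye(len(rsids)))


def harmonise(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    maf_ambiguity_threshold: float = 0.42,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align exposure and outcome associations to a common effect allele.

    For each rsid shared between the two tables the outcome record is brought
    onto the exposure's allele orientation:

    * same allele pair, same orientation — kept as-is;
    * same pair, swapped — the outcome beta is sign-flipped and its eaf
      becomes ``1 - eaf``;
    * complementary-strand pair (e.g. A/G vs T/C) — complemented first, then
      the above;
    * palindromic (A/T or G/C) — orientation resolved by allele frequency
      only when both eafs sit on the same side of 0.5 and both are outside
      the ambiguity band ``[t, 1-t]``; otherwise dropped as
      ``palindromic-unresolved``;
    * irreconcilable allele pairs — dropped as ``mismatch``.

    Returns the harmonised pair table (columns :data:`PAIR_COLUMNS`) and an
    exclusion log.
    """
    t = float(maf_ambiguity_threshold)
    exp = exposure.set_index("rsid", drop=False)
    out = outcome.set_index("rsid", drop=False)
    shared = [r for r in exp.index if r in out.index]

    rows = []
    excluded: list[tuple[str, str]] = []
    for rsid in shared:
        e, o = exp.loc[rsid], out.loc[rsid]
        ea_e, oa_e = e["ea"], e["oa"]
        ea_o, oa_o = o["ea"], o["oa"]
        palindromic = oa_e == _COMPLEMENT[ea_e]

        beta_o, eaf_o = float(o["beta"]), o["eaf"]
        flipped = False

        if palindromic:
            if {ea_o, oa_o} != {ea_e, oa_e}:
                excluded.append((rsid, "mismatch"))
                continue
            # align the reported labels first (a plain allele swap is not a
            # strand ambiguity), then demand frequency concordance outside the
            # ambiguity band: a residual discordance would mean a true strand
            # flip, which allele labels cannot reveal for a palindrome
            if ea_o == oa_e:
                beta_o = -beta_o
                if not pd.isna(eaf_o):
                    eaf_o = 1 - eaf_o
                flipped = True
            eaf_e = e["eaf"]
            if (
                pd.isna(eaf_e) or pd.isna(eaf_o)
                or t <= eaf_e <= 1 - t or t <= eaf_o <= 1 - t
                or (eaf_e < 0.5) != (eaf_o < 0.5)
            ):
                excluded.append((rsid, "palindromic-unresolved"))
                continue
        else:
            if {ea_o, oa_o} == {_COMPLEMENT[ea_e], _COMPLEMENT[oa_e]} and \
                    {ea_o, oa_o} != {ea_e, oa_e}:
                ea_o, oa_o = _COMPLEMENT[ea_o], _COMPLEMENT[oa_o]
            if (ea_o, oa_o) == (ea_e, oa_e):
                pass
            elif (ea_o, oa_o) == (oa_e, ea_e):
                beta_o = -beta_o
                if not pd.isna(eaf_o):
                    eaf_o = 1 - eaf_o
                flipped = True
            else:
                excluded.append((rsid, "mismatch"))
                continue

        rows.append({
            "rsid": rsid, "chr": e["chr"], "pos": e["pos"], "ea": ea_e, "oa": oa_e,
            "beta_exp": float(e["beta"]), "se_exp": float(e["se"]),
            "eaf_exp": e["eaf"], "n_exp": float(e["n"]),
            "beta_out": beta_o, "se_out": float(o["se"]),
            "eaf_out": eaf_o, "n_out": float(o["n"]),
            "palindromic": bool(palindromic), "flipped": flipped,
        })

    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return pairs, _exclusion_log(excluded)


def clump(
    assocs: pd.DataFrame,
    ld: LdMatrix | None = None,
    window_kb: float = 500,
    r2_threshold: float = 0.001,
    p_threshold: float = 5e-8,
) -> list[str]:
    """Greedy p-value clumping into an independent set of index variants.

    Repeatedly select the remaining variant with the smallest p-value below
    ``p_threshold``, then discard every remaining variant on the same
    chromosome that lies within ``window_kb`` kb of it AND has r² at or above
    ``r2_threshold`` with it.  Without an LD matrix the distance criterion
    alone applies (logged loudly, since that is a coarser rule).  Ties in
    p-value break by (chr, pos) ascending.  Returned rsids are in selection
    order.
    """
    if ld is None and len(assocs):
        warnings.warn(
            "clumping without an LD matrix: using the distance criterion only",
            stacklevel=2,
        )
    df = assocs.loc[assocs["p"] < p_threshold, ["rsid", "chr", "pos", "p"]].copy()
    df = df.sort_values(["p", "chr", "pos"], kind="mergesort").reset_index(drop=True)

    rsids = df["rsid"].astype(str).to_numpy()
    chroms = df["chr"].to_numpy()
    pos = df["pos"].to_numpy(dtype=float)
    retained: list[str] = []
    alive = np.ones(len(df), dtype=bool)
    window_bp = window_kb * 1000.0
    for i in range(len(df)):
        if not alive[i]:
            continue
        retained.append(rsids[i])
        alive[i] = False
        near = alive & (chroms == chroms[i]) & (np.abs(pos - pos[i]) <= window_bp)
        for j in np.nonzero(near)[0]:
            if ld is None or ld.lookup(rsids[i], rsids[j]) >= r2_threshold:
                alive[j] = False
    return retained


def steiger_filter(
    pairs: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain pairs whose instrument explains significantly more variance in
    the exposure than in the outcome.

    Variance explained per trait is the pseudo-r² ``Z² / (Z² + n)`` with
    ``Z = beta/se``.  The directionality test is one-sided on the difference
    of Fisher z-transformed correlations ``r = sqrt(r²)``, with variance
    ``1/(n_exp - 3) + 1/(n_out - 3)``.  A pair is kept iff
    ``r²_exp > r²_out`` and the test's p-value is below ``alpha``.  Pairs
    with a sample size of 3 or less on either side are dropped
    (``n-too-small``).
    """
    excluded: list[tuple[str, str]] = []
    keep = []
    for _, row in pairs.iterrows():
        rsid = str(row["rsid"])
        n_exp, n_out = float(row["n_exp"]), float(row["n_out"])
        if n_exp <= 3 or n_out <= 3:
            excluded.append((rsid, "n-too-small"))
            continue
        z_exp = row["beta_exp"] / row["se_exp"]
        z_out = row["beta_out"] / row["se_out"]
        r2_exp = z_exp**2 / (z_exp**2 + n_exp)
        r2_out = z_out**2 / (z_out**2 + n_out)
        if not r2_exp > r2_out:
            excluded.append((rsid, "steiger-direction"))
            continue
        fz = np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))
        se_fz = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
        p = float(stats.norm.sf(fz / se_fz))
        if p < alpha:
            keep.append(row)
        else:
            excluded.append((rsid, "steiger-not-significant"))
    retained = pd.DataFrame(keep, columns=pairs.columns).reset_index(drop=True)
    return retained, _exclusion_log(excluded)
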