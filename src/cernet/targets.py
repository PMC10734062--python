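"""miRNA -> transcript interaction evidence.

Two sources are supported: a canonical seed-match predictor (6mer, 7mer-A1,
7mer-m8, 8mer sites) and import of externally predicted tables (e.g.
miRanda / TargetScan exports). Site definitions, 5'->3' on the target:

* 6mer      — reverse complement of miRNA nt 2-7
* 7mer-A1   — 6mer followed by an A (opposite miRNA nt 1)
* 7mer-m8   — reverse complement of miRNA nt 2-8
* 8mer      — 7mer-m8 followed by an A

Each matching window is reported once, as its highest class. circRNA
sequences are scanned as the back-splice-joined doubled sequence, keeping
each linear site once plus any site spanning the junction.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO

from .errors import ParseError, UserError
from .io import validate_target_table

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_SITE_RANK = {"6mer": 1, "7mer-A1": 2, "7mer-m8": 3, "8mer": 4}


def _normalize_rna(seq: str, label: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ParseError(f"{label}: non-nucleotide character(s) {sorted(bad)}")
    return s


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def read_fasta(path) -> dict:
    """id -> sequence, uppercased, T converted to U."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = _normalize_rna(str(rec.seq), rec.id)
    return records


def find_seed_sites(mirna: str, transcript: str, circular: bool = False) -> list:
    """All canonical seed sites of one miRNA in one transcript.

    Returns (site_type, 1-based site start) tuples. Positions refer to the
    linear sequence; circular transcripts may yield junction-spanning sites
    whose windows wrap past the 3' end.
    """
    if len(mirna) < 8:
        raise UserError("miRNA shorter than 8 nt has no defined seed")
    core = _revcomp(mirna[1:7])          # rc of nt 2-7, the 6mer core
    m8 = _COMPLEMENT[mirna[7]]           # target base pairing miRNA nt 8
    body_len = len(transcript)
    scan = transcript + transcript if circular else transcript
    sites = []
    start = 0
    while True:
        k = scan.find(core, start)
        if k == -1:
            break
        start = k + 1
        has_m8 = k >= 1 and scan[k - 1] == m8
        has_a1 = k + 6 < len(scan) and scan[k + 6] == "A"
        if has_m8 and has_a1:
            site, pos = "8mer", k - 1
        elif has_m8:
            site, pos = "7mer-m8", k - 1
        elif has_a1:
            site, pos = "7mer-A1", k
        else:
            site, pos = "6mer", k
        if circular and pos >= body_len:
            continue  # duplicate of a site already seen in the first copy
        sites.append((site, pos + 1))
    return sites


def predict_targets_seed(
    mirnas: dict,
    transcripts: dict,
    site_types=("8mer", "7mer-m8", "7mer-A1", "6mer"),
    circular_ids=(),
) -> pd.DataFrame:
    """Scan every transcript for canonical seed sites of every miRNA.

    Parameters
    ----------
    mirnas, transcripts
        id -> sequence mappings (or paths already read via :func:`read_fasta`).
        Case- and U/T-insensitive.
    site_types
        Site classes to report; a window is always classified as its highest
        class first, so excluding e.g. 6mer does not re-report those windows.
    circular_ids
        Transcript ids to scan as back-splice-joined circles.

    Returns a validated target table with score = site-class rank (8mer=4 ..
    6mer=1) and source ``seed_match``.
    """
    unknown = set(site_types) - set(_SITE_RANK)
    if unknown:
        raise UserError(f"unknown site type(s): {sorted(unknown)}")
    circular_ids = set(circular_ids)
    rows = []
    for mid in sorted(mirnas):
        mseq = _normalize_rna(mirnas[mid], mid)
        for tid in sorted(transcripts):
            tseq = _normalize_rna(transcripts[tid], tid)
            for site, pos in find_seed_sites(mseq, tseq, circular=tid in circular_ids):
                if site in site_types:
                    rows.append(
                        {
                            "mirna_id": mid,
                            "target_id": tid,
                            "site_type": site,
                            "position": pos,
                            "score": _SITE_RANK[site],
                            "source": "seed_match",
                        }
                    )
    df = pd.DataFrame(
        rows, columns=["mirna_id", "target_id", "site_type", "position", "score", "source"]
    )
    return validate_target_table(df)


def merge_target_tables(tables, mode: str = "union") -> pd.DataFrame:
    """Combine evidence tables into one row per (miRNA, target) pair.

    union: pairs present in any source; intersection: pairs present in every
    source. The best site/score among the pair's records is kept and
    provenance is retained as a semicolon-joined source list.
    """
    tables = [validate_target_table(t) for t in tables]
    if not tables:
        raise UserError("no target tables to merge")
    if mode not in ("union", "intersection"):
        raise UserError(f"unknown merge mode {mode!r}")
    pair_sets = [set(zip(t["mirna_id"], t["target_id"])) for t in tables]
    keep = set.union(*pair_sets) if mode == "union" else set.intersection(*pair_sets)
    stacked = pd.concat(tables, ignore_index=True)
    stacked = stacked[
        [p in keep for p in zip(stacked["mirna_id"], stacked["target_id"])]
    ]
    rows = []
    for (mid, tid), grp in stacked.groupby(["mirna_id", "target_id"], sort=True):
        ranks = grp["site_type"].map(lambda s: _SITE_RANK.get(s, 0))
        best = grp.loc[ranks.idxmax()]
        rows.append(
            {
                "mirna_id": mid,
                "target_id": tid,
                "site_type": best["site_type"],
                "position": best["position"],
                "score": grp["score"].max(),
                "source": ";".join(sorted(set(grp["source"]))),
            }
        )
    return pd.DataFrame(
        rows, columns=["mirna_id", "target_id", "site_type", "position", "score", "source"]
    )
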