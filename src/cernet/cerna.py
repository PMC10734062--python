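"""ceRNA circuit assembly and biological filtering.

A circuit is a retained co-expression edge (sponge lnc/circRNA, mRNA) whose
endpoints share at least ``min_shared`` predicted miRNAs. Circuits are keyed
by the (sponge, mRNA) pair; the shared miRNAs are recorded exhaustively as
an attribute. Downstream filters restrict to sponges whose host genes escape
X inactivation and to mRNAs in a user-supplied gene set (e.g. heart
development), mirroring the dosage-driven regulatory hypothesis: an X-escape
sponge is halved in 45,X cells, freeing or sequestering its miRNAs and
thereby shifting autosomal targets.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .errors import UserError, ValidationError
from .io import CeRNACircuit, validate_target_table


def _targets_by_mirna(targets: pd.DataFrame) -> dict:
    by = {}
    for mid, tid in zip(targets["mirna_id"], targets["target_id"]):
        by.setdefault(mid, set()).add(tid)
    return by


def assemble_circuits(edges, targets: pd.DataFrame, min_shared: int = 1) -> list:
    """One circuit per co-expression edge with >= min_shared shared miRNAs.

    ``edges`` must already be threshold-filtered (r and P); ``targets`` is a
    validated miRNA->target table covering both sponges and mRNAs.
    """
    if min_shared < 1:
        raise UserError("min_shared must be >= 1")
    targets = validate_target_table(targets)
    mirnas_of: dict = {}
    for mid, tid in zip(targets["mirna_id"], targets["target_id"]):
        mirnas_of.setdefault(tid, set()).add(mid)
    circuits = []
    for e in edges:
        shared = mirnas_of.get(e.sponge_feature_id, set()) & mirnas_of.get(
            e.mrna_feature_id, set()
        )
        if len(shared) >= min_shared:
            circuits.append(
                CeRNACircuit(
                    sponge_feature_id=e.sponge_feature_id,
                    mrna_feature_id=e.mrna_feature_id,
                    shared_mirna_ids=tuple(sorted(shared)),
                    pcc=e.pcc,
                    pcc_p=e.p_value,
                    contrast=e.contrast,
                )
            )
    return circuits


def shared_mirna_enrichment(
    sponge_mirna_count: int,
    mrna_mirna_count: int,
    shared_count: int,
    mirna_universe_size: int,
) -> float:
    """Hypergeometric upper tail P(X >= shared) for the shared-miRNA overlap.

    Models the mRNA's miRNAs as a draw of size ``mrna_mirna_count`` from a
    universe of ``mirna_universe_size`` miRNAs of which
    ``sponge_mirna_count`` also target the sponge.
    """
    if shared_count > min(sponge_mirna_count, mrna_mirna_count):
        raise UserError("shared count exceeds an endpoint's target count")
    if mirna_universe_size < max(sponge_mirna_count, mrna_mirna_count):
        raise UserError("miRNA universe smaller than an endpoint's target count")
    if shared_count == 0:
        return 1.0
    return float(
        stats.hypergeom.sf(
            shared_count - 1, mirna_universe_size, sponge_mirna_count, mrna_mirna_count
        )
    )


def annotate_enrichment(circuits, targets: pd.DataFrame, mirna_universe_size: int) -> list:
    """Populate ``shared_mirna_enrichment_p`` on each circuit (optional filter)."""
    targets = validate_target_table(targets)
    mirnas_of: dict = {}
    for mid, tid in zip(targets["mirna_id"], targets["target_id"]):
        mirnas_of.setdefault(tid, set()).add(mid)
    out = []
    for c in circuits:
        p = shared_mirna_enrichment(
            len(mirnas_of.get(c.sponge_feature_id, ())),
            len(mirnas_of.get(c.mrna_feature_id, ())),
            len(c.shared_mirna_ids),
            mirna_universe_size,
        )
        out.append(
            CeRNACircuit(
                c.sponge_feature_id, c.mrna_feature_id, c.shared_mirna_ids,
                c.pcc, c.pcc_p, c.contrast, shared_mirna_enrichment_p=p,
                sponge_host_escapes_xci=c.sponge_host_escapes_xci,
                mrna_in_filter_set=c.mrna_in_filter_set,
            )
        )
    return out


def filter_circuits(
    circuits,
    annotation: pd.DataFrame,
    escape_required: bool = True,
    mrna_filter_set=None,
) -> list:
    """Keep circuits with an XCI-escaping sponge host and/or a filtered mRNA.

    ``mrna_filter_set`` is matched against mRNA gene symbols; ``None``
    disables that filter (an *empty* set keeps nothing). Flags are populated
    on every returned circuit.
    """
    ann = annotation.set_index("feature_id")
    out = []
    for c in circuits:
        for endpoint in (c.sponge_feature_id, c.mrna_feature_id):
            if endpoint not in ann.index:
                raise ValidationError(f"circuit endpoint missing annotation: {endpoint!r}")
        escapes = bool(
            ann.loc[c.sponge_feature_id, "chromosome"] == "X"
            and ann.loc[c.sponge_feature_id, "xci_escape"]
        )
        symbol = ann.loc[c.mrna_feature_id, "gene_symbol"]
        in_set = None if mrna_filter_set is None else symbol in set(mrna_filter_set)
        if escape_required and not escapes:
            continue
        if mrna_filter_set is not None and not in_set:
            continue
        out.append(
            CeRNACircuit(
                c.sponge_feature_id, c.mrna_feature_id, c.shared_mirna_ids,
                c.pcc, c.pcc_p, c.contrast,
                shared_mirna_enrichment_p=c.shared_mirna_enrichment_p,
                sponge_host_escapes_xci=escapes,
                mrna_in_filter_set=in_set,
            )
        )
    return out
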