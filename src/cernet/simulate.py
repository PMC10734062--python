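"""Synthetic multi-class expression bundles with planted ceRNA circuits.

The generator emulates a 2 genotype (WT 46,XX vs TS 45,X) x 2 cell state
(iPSC vs CM) x n-lines design on the log2 scale:

    log2 expr = baseline(feature)
              + diff_effect(feature) * 1[CM]            (CM-regulated subset)
              + log2(dosage_factor) * 1[TS & X-escape]  (haploinsufficiency)
              + line_intercept(line)                    (pairing structure)
              + Normal(0, noise_sd)

Planted ceRNA circuits couple an mRNA target to its sponge:

    target log2 = baseline(target) + beta * (sponge log2 - sponge mean)
                + Normal(0, noise_sd)

so with beta > 0 the pair is co-expressed and the target inherits the
sponge's differentiation and dosage shifts scaled by beta. Planted sponges
are X-linked, XCI-escaping and CM-regulated; planted targets are autosomal
mRNAs with no effect of their own. The emitted target table contains the
planted (miRNA -> sponge, miRNA -> mRNA) pairs plus uniformly sampled decoy
interactions at ``decoy_ratio`` decoys per true pair.

Matrices are emitted on the linear scale (2**log2), so group-mean ratios of
noise-free escape features equal the dosage factor exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UserError, ValidationError
from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    concat_matrices,
    validate_feature_annotation,
    validate_target_table,
    write_expression_matrix,
    write_feature_annotation,
    write_gene_sets,
    write_sample_sheet,
    write_target_table,
)

AUTOSOMES = tuple(str(i) for i in range(1, 23))


@dataclass
class SimulationConfig:
    """Stated world of the simulator; defaults mirror the 3+3-line design."""

    n_lines_per_genotype: int = 3
    n_mrna: int = 1200
    n_lncrna: int = 700
    n_circrna: int = 400
    n_mirnas: int = 800
    frac_cm_regulated: float = 0.10
    diff_effect_mean: float = 2.0
    diff_effect_sd: float = 0.5
    ts_dosage_factor: float = 0.5
    frac_chrx: float = 0.05
    frac_escape_of_x: float = 0.3
    n_planted_circuits: int = 10
    mirnas_per_circuit: int = 1
    circuit_beta: float = 0.9
    noise_sd: float = 0.3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    line_sd: float = 0.1
    decoy_ratio: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lines_per_genotype", "n_mrna", "n_lncrna", "n_circrna", "n_mirnas"):
            if getattr(self, name) < 1:
                raise UserError(f"{name} must be positive")
        if not 0 < self.ts_dosage_factor <= 1:
            raise UserError("ts_dosage_factor must lie in (0, 1]")
        if self.noise_sd < 0 or self.line_sd < 0:
            raise UserError("standard deviations must be non-negative")
        if not 0 <= self.circuit_beta <= 2:
            raise UserError("circuit_beta must lie in [0, 2]")
        if self.n_planted_circuits < 0 or self.mirnas_per_circuit < 1:
            raise UserError("invalid circuit counts")
        if self.n_planted_circuits > self.n_lncrna + self.n_circrna:
            raise UserError("more planted circuits than available sponge features")
        if self.n_planted_circuits > self.n_mrna:
            raise UserError("more planted circuits than available mRNA targets")
        if self.n_planted_circuits * self.mirnas_per_circuit > self.n_mirnas:
            raise UserError("not enough miRNAs for the requested circuits")
        if not 0 <= self.frac_cm_regulated <= 1:
            raise UserError("frac_cm_regulated must lie in [0, 1]")


@dataclass
class TruthManifest:
    """Ground truth for scoring: planted effects, circuits, escape features."""

    de_features: dict  # contrast -> {feature_id: expected log2 effect}
    circuits: list     # [{sponge_id, mirna_ids, mrna_id, beta}, ...]
    escape_features: list

    def circuit_pairs(self) -> set:
        return {(c["sponge_id"], c["mrna_id"]) for c in self.circuits}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        d = json.loads(text)
        return cls(d["de_features"], d["circuits"], d["escape_features"])


@dataclass
class SimulatedBundle:
    """Everything one run emits: matrices, annotation, targets, truth, sets."""

    matrices: dict  # rna_class -> ExpressionMatrix (linear scale)
    annotation: pd.DataFrame
    targets: pd.DataFrame
    truth: TruthManifest
    gene_sets: GeneSetCollection
    config: SimulationConfig

    def combined(self) -> ExpressionMatrix:
        return concat_matrices(
            [self.matrices[c] for c in ("mRNA", "lncRNA", "circRNA")]
        )

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for cls, m in self.matrices.items():
            write_expression_matrix(m, directory / f"expression_{cls}.tsv")
        write_sample_sheet(
            self.matrices["mRNA"].sample_groups, directory / "samples.tsv"
        )
        write_feature_annotation(self.annotation, directory / "annotation.tsv")
        write_target_table(self.targets, directory / "targets.tsv")
        write_gene_sets(self.gene_sets, directory / "gene_sets.gmt")
        (directory / "truth.json").write_text(self.truth.to_json())


def _feature_ids(config: SimulationConfig):
    mrna = [f"mRNA_{i:05d}" for i in range(1, config.n_mrna + 1)]
    lnc = [f"lnc-HL{i:04d}-1:1" for i in range(1, config.n_lncrna + 1)]
    circ = [f"circ_{i:07d}" for i in range(1, config.n_circrna + 1)]
    return mrna, lnc, circ


def generate_dataset(config: SimulationConfig) -> SimulatedBundle:
    """Deterministically generate one bundle from a config (seed included)."""
    ss = np.random.SeedSequence(config.seed)
    rng_feat, rng_expr, rng_targets, rng_sets = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    mrna_ids, lnc_ids, circ_ids = _feature_ids(config)
    all_ids = mrna_ids + lnc_ids + circ_ids
    n_features = len(all_ids)
    classes = (
        ["mRNA"] * len(mrna_ids) + ["lncRNA"] * len(lnc_ids) + ["circRNA"] * len(circ_ids)
    )
    index = pd.Index(all_ids, name="feature_id")
    is_mrna = np.array([c == "mRNA" for c in classes])
    is_sponge_class = ~is_mrna

    # --- chromosome / escape assignment -----------------------------------
    on_x = rng_feat.random(n_features) < config.frac_chrx
    chromosome = np.where(on_x, "X", rng_feat.choice(AUTOSOMES, size=n_features))
    escape = on_x & (rng_feat.random(n_features) < config.frac_escape_of_x)

    # --- differentiation effects -------------------------------------------
    cm_regulated = rng_feat.random(n_features) < config.frac_cm_regulated
    signs = rng_feat.choice([-1.0, 1.0], size=n_features)
    magnitudes = rng_feat.normal(config.diff_effect_mean, config.diff_effect_sd, n_features)
    diff_effect = np.where(cm_regulated, signs * magnitudes, 0.0)

    # --- plant circuits ------------------------------------------------------
    sponge_pool = np.flatnonzero(is_sponge_class)
    target_pool = np.flatnonzero(is_mrna)
    sponge_idx = rng_feat.choice(sponge_pool, size=config.n_planted_circuits, replace=False)
    target_idx = rng_feat.choice(target_pool, size=config.n_planted_circuits, replace=False)
    # sponges: X-linked, escaping, CM-regulated (fresh effect draw if needed)
    chromosome[sponge_idx] = "X"
    escape[sponge_idx] = True
    need_effect = sponge_idx[~cm_regulated[sponge_idx]]
    cm_regulated[sponge_idx] = True
    diff_effect[need_effect] = rng_feat.choice([-1.0, 1.0], size=len(need_effect)) * (
        rng_feat.normal(config.diff_effect_mean, config.diff_effect_sd, len(need_effect))
    )
    # targets: autosomal, no effect of their own
    chromosome[target_idx] = rng_feat.choice(AUTOSOMES, size=config.n_planted_circuits)
    escape[target_idx] = False
    cm_regulated[target_idx] = False
    diff_effect[target_idx] = 0.0

    # --- samples -------------------------------------------------------------
    lines = [f"W{i}" for i in range(1, config.n_lines_per_genotype + 1)] + [
        f"T{i}" for i in range(1, config.n_lines_per_genotype + 1)
    ]
    genotype_of = {ln: ("WT" if ln.startswith("W") else "TS") for ln in lines}
    sample_rows = []
    for ln in lines:
        for state in ("iPSC", "CM"):
            sample_rows.append(
                {"sample_id": f"{ln}_{state}", "genotype": genotype_of[ln],
                 "state": state, "line_id": ln}
            )
    groups = pd.DataFrame(sample_rows).set_index("sample_id")
    sample_ids = list(groups.index)
    is_cm = (groups["state"] == "CM").to_numpy(dtype=float)
    is_ts = (groups["genotype"] == "TS").to_numpy(dtype=float)

    # --- expression ----------------------------------------------------------
    baseline = rng_expr.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, n_features
    )
    line_intercept = rng_expr.normal(0.0, config.line_sd, len(lines))
    line_of_sample = np.array([lines.index(groups.loc[s, "line_id"]) for s in sample_ids])
    noise = rng_expr.normal(0.0, config.noise_sd, (n_features, len(sample_ids)))

    log2 = (
        baseline[:, None]
        + np.outer(diff_effect, is_cm)
        + np.log2(config.ts_dosage_factor) * np.outer(escape.astype(float), is_ts)
        + line_intercept[line_of_sample][None, :]
        + noise
    )
    # overwrite planted targets with the coupling model
    for sp, tg in zip(sponge_idx, target_idx):
        sponge_row = log2[sp]
        log2[tg] = (
            baseline[tg]
            + config.circuit_beta * (sponge_row - sponge_row.mean())
            + noise[tg]
        )

    values = pd.DataFrame(2.0 ** log2, index=index, columns=sample_ids)

    # --- annotation -----------------------------------------------------------
    def host_of(fid: str, cls: str) -> str:
        if cls == "lncRNA":
            return fid.split("-")[1]
        if cls == "circRNA":
            return f"HC{int(fid.split('_')[1]):04d}"
        return ""

    symbols = [
        f"GENE{i + 1:05d}" if cls == "mRNA" else fid
        for i, (fid, cls) in enumerate(zip(all_ids, classes))
    ]
    annotation = validate_feature_annotation(
        pd.DataFrame(
            {
                "feature_id": all_ids,
                "rna_class": classes,
                "gene_symbol": symbols,
                "host_gene": [host_of(f, c) for f, c in zip(all_ids, classes)],
                "chromosome": chromosome,
                "xci_escape": escape,
            }
        )
    )
    symbol_of = dict(zip(all_ids, symbols))

    # --- target table -----------------------------------------------------------
    mirna_ids = [f"miR-{i:04d}" for i in range(1, config.n_mirnas + 1)]
    chosen = rng_targets.choice(
        config.n_mirnas,
        size=config.n_planted_circuits * config.mirnas_per_circuit,
        replace=False,
    )
    circuits = []
    true_pairs = []
    for k, (sp, tg) in enumerate(zip(sponge_idx, target_idx)):
        ms = sorted(
            mirna_ids[j]
            for j in chosen[k * config.mirnas_per_circuit:(k + 1) * config.mirnas_per_circuit]
        )
        circuits.append(
            {
                "sponge_id": all_ids[sp],
                "mirna_ids": ms,
                "mrna_id": all_ids[tg],
                "beta": config.circuit_beta,
            }
        )
        for m in ms:
            true_pairs.append((m, all_ids[sp]))
            true_pairs.append((m, all_ids[tg]))
    n_decoys = int(round(config.decoy_ratio * len(true_pairs)))
    n_cells = config.n_mirnas * n_features
    if n_decoys + len(true_pairs) > n_cells:
        raise UserError("decoy_ratio too large for the miRNA x feature universe")
    taken = {m * n_features + all_ids.index(t) for m, t in (
        (mirna_ids.index(mm), tt) for mm, tt in true_pairs
    )}
    decoys = []
    while len(decoys) < n_decoys:
        draw = rng_targets.choice(n_cells, size=2 * (n_decoys - len(decoys)), replace=False)
        for cell in draw:
            if cell not in taken:
                taken.add(cell)
                decoys.append((mirna_ids[cell // n_features], all_ids[cell % n_features]))
                if len(decoys) == n_decoys:
                    break
    targets = validate_target_table(
        pd.DataFrame(
            {
                "mirna_id": [m for m, _ in true_pairs + decoys],
                "target_id": [t for _, t in true_pairs + decoys],
                "site_type": "imported",
                "position": pd.NA,
                "score": np.nan,
                "source": "imported_1",
            }
        )
    )

    # --- truth manifest -----------------------------------------------------------
    beta = config.circuit_beta
    dosage_shift = float(np.log2(config.ts_dosage_factor))
    diff_truth = {all_ids[i]: float(diff_effect[i]) for i in np.flatnonzero(cm_regulated)}
    for sp, tg in zip(sponge_idx, target_idx):
        if beta != 0:
            diff_truth[all_ids[tg]] = float(beta * diff_effect[sp])
    ts_truth = {all_ids[i]: dosage_shift for i in np.flatnonzero(escape)}
    for sp, tg in zip(sponge_idx, target_idx):
        if beta != 0 and dosage_shift != 0:
            ts_truth[all_ids[tg]] = beta * dosage_shift
    truth = TruthManifest(
        de_features={
            "WT_CM_vs_WT_iPSC": {k: v for k, v in diff_truth.items() if v != 0},
            "TS_CM_vs_TS_iPSC": {k: v for k, v in diff_truth.items() if v != 0},
            "TS_CM_vs_WT_CM": {k: v for k, v in ts_truth.items() if v != 0},
        },
        circuits=circuits,
        escape_features=[all_ids[i] for i in np.flatnonzero(escape)],
    )

    # --- gene sets: heart-development stand-in + random sets -----------------------
    planted_symbols = sorted(symbol_of[all_ids[tg]] for tg in target_idx)
    other_mrna = [s for s in symbols[: len(mrna_ids)] if s not in set(planted_symbols)]
    n_extras = min(max(len(planted_symbols), 10), len(other_mrna))
    extras = sorted(
        str(s) for s in rng_sets.choice(other_mrna, size=n_extras, replace=False)
    )
    sets = {"HEART_DEVELOPMENT": sorted(planted_symbols + extras)}
    descriptions = {
        "HEART_DEVELOPMENT": "synthetic stand-in for a heart-development gene set"
    }
    for i in range(1, 4):
        members = sorted(
            str(s)
            for s in rng_sets.choice(symbols[: len(mrna_ids)], size=25, replace=False)
        )
        sets[f"RANDOM_SET_{i}"] = members
        descriptions[f"RANDOM_SET_{i}"] = "uniformly sampled mRNA gene symbols"
    gene_sets = GeneSetCollection(sets, descriptions)

    # split per class, preserving feature order
    matrices = {}
    for cls, ids in (("mRNA", mrna_ids), ("lncRNA", lnc_ids), ("circRNA", circ_ids)):
        matrices[cls] = ExpressionMatrix(values.loc[ids], groups, scale="linear")

    bundle = SimulatedBundle(matrices, annotation, targets, truth, gene_sets, config)
    _check_truth_consistency(bundle)
    return bundle


def _check_truth_consistency(bundle: SimulatedBundle) -> None:
    """Every planted id must exist in the emitted matrices/annotation."""
    known = set(bundle.annotation["feature_id"])
    emitted = set()
    for m in bundle.matrices.values():
        emitted.update(m.feature_ids)
    if known != emitted:
        raise ValidationError("annotation and matrices disagree on feature ids")
    for contrast, effects in bundle.truth.de_features.items():
        missing = set(effects) - known
        if missing:
            raise ValidationError(f"{contrast}: planted ids missing: {sorted(missing)[:3]}")
    for c in bundle.truth.circuits:
        if c["sponge_id"] not in known or c["mrna_id"] not in known:
            raise ValidationError(f"planted circuit references unknown feature: {c}")


def score_recovery(called_circuits, truth: TruthManifest):
    """(sensitivity, false discovery proportion) of called vs planted circuits.

    Matching is on (sponge, mRNA) pairs; ``called_circuits`` may be
    :class:`~cernet.io.CeRNACircuit` objects or bare pairs.
    """
    if called_circuits is None or truth is None:
        raise UserError("score_recovery requires called circuits and a truth manifest")
    called = set()
    for c in called_circuits:
        called.add(c.pair if hasattr(c, "pair") else (c[0], c[1]))
    planted = truth.circuit_pairs()
    if not planted:
        raise UserError("truth manifest has no planted circuits")
    sensitivity = len(called & planted) / len(planted)
    fdp = len(called - planted) / max(len(called), 1)
    return sensitivity, fdp
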