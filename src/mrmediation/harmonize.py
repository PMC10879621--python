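"""Allele harmonization of outcome summary statistics to exposure instruments.

Outcome records are aligned to the exposure's effect allele, resolving
swapped orientations (sign flip), strand flips (base complement) and
palindromic A/T or C/G variants, whose orientation is inferred from the
effect-allele frequency on both sides. A palindrome whose frequency lies in
the ambiguity zone around 0.5 on either side is dropped rather than guessed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ACTION_KEPT = "kept"
ACTION_FLIP = "sign_flipped"
ACTION_COMP = "strand_complemented"
ACTION_FLIP_COMP = "sign_flipped_and_complemented"
ACTION_DROP_PALIN = "dropped_palindromic_ambiguous"
ACTION_DROP_MISMATCH = "dropped_allele_mismatch"

#: columns of a harmonized instrument table
HARMONIZED_COLUMNS = [
    "snp_id", "beta_exp", "se_exp", "eaf_exp", "beta_out", "se_out", "eaf_out",
    "action",
]


def is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def retained(table: pd.DataFrame) -> pd.DataFrame:
    """Rows of a harmonized table that survived (action not 'dropped_*')."""
    return table[~table["action"].str.startswith("dropped")]


def _eaf_ok(eaf, lo: float, hi: float) -> bool:
    return eaf is not None and not pd.isna(eaf) and not (lo <= eaf <= hi)


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              eaf_ambiguity: float = 0.08) -> pd.DataFrame:
    """Align outcome records to the exposure effect alleles.

    Parameters
    ----------
    exposure, outcome
        Canonical summary-statistics tables (see :mod:`mrmediation.sumstats`);
        matched on ``snp_id`` only. Unmatched exposure SNPs are dropped with
        a log entry.
    eaf_ambiguity
        Half-width of the palindrome ambiguity zone around 0.5. The default
        0.08 gives the zone [0.42, 0.58].

    Returns
    -------
    A harmonized instrument table with one row per matched SNP and an
    ``action`` column recording what was done; dropped rows stay in the
    table for audit and are excluded by :func:`retained`.
    """
    lo, hi = 0.5 - eaf_ambiguity, 0.5 + eaf_ambiguity
    out_by_id = {r.snp_id: r for r in outcome.itertuples(index=False)}
    rows = []
    n_unmatched = 0
    for e in exposure.itertuples(index=False):
        o = out_by_id.get(e.snp_id)
        if o is None:
            n_unmatched += 1
            log.info("SNP %s has no outcome record; dropped", e.snp_id)
            continue
        e1, e2 = e.effect_allele, e.other_allele
        o1, o2 = o.effect_allele, o.other_allele
        beta_out, eaf_out = float(o.beta), o.eaf

        if is_palindromic(e1, e2):
            if {o1, o2} != {e1, e2}:
                action = ACTION_DROP_MISMATCH
            elif _eaf_ok(e.eaf, lo, hi) and _eaf_ok(o.eaf, lo, hi):
                same_side = (e.eaf < 0.5) == (eaf_out < 0.5)
                if same_side:
                    # the outcome file may label the pair in either order; the
                    # frequency, not the allele label, carries the orientation
                    action = ACTION_KEPT if o1 == e1 else ACTION_COMP
                else:
                    action = ACTION_FLIP if o1 != e1 else ACTION_FLIP_COMP
                    beta_out = -beta_out
                    eaf_out = np.nan if pd.isna(eaf_out) else 1.0 - eaf_out
            else:
                action = ACTION_DROP_PALIN
                if e.eaf is None or pd.isna(e.eaf) or o.eaf is None or pd.isna(o.eaf):
                    log.warning("palindromic SNP %s lacks eaf; dropped", e.snp_id)
        elif (o1, o2) == (e1, e2):
            action = ACTION_KEPT
        elif (o1, o2) == (e2, e1):
            action = ACTION_FLIP
            beta_out = -beta_out
            eaf_out = np.nan if pd.isna(eaf_out) else 1.0 - eaf_out
        elif (COMPLEMENT.get(o1), COMPLEMENT.get(o2)) == (e1, e2):
            action = ACTION_COMP
        elif (COMPLEMENT.get(o1), COMPLEMENT.get(o2)) == (e2, e1):
            action = ACTION_FLIP_COMP
            beta_out = -beta_out
            eaf_out = np.nan if pd.isna(eaf_out) else 1.0 - eaf_out
        else:
            action = ACTION_DROP_MISMATCH

        rows.append({
            "snp_id": e.snp_id,
            "beta_exp": float(e.beta), "se_exp": float(e.se),
            "eaf_exp": np.nan if pd.isna(e.eaf) else float(e.eaf),
            "beta_out": beta_out, "se_out": float(o.se),
            "eaf_out": np.nan if eaf_out is None or pd.isna(eaf_out) else float(eaf_out),
            "action": action,
        })
    if n_unmatched:
        log.info("%d exposure SNP(s) had no outcome match", n_unmatched)
    table = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    n_drop = int(table["action"].str.startswith("dropped").sum()) if len(table) else 0
    log.info("harmonized %d SNPs (%d dropped)", len(table), n_drop)
    return table
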