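"""Stability records and the dataset-curation protocol.

Sign convention (fixed throughout the package): ddG < 0 destabilizing,
ddG > 0 stabilizing; exactly 0 is assigned to the destabilizing class.
Class imbalance is countered by appending hypothetical reverse mutations
(mut -> wt with -ddG), except those whose reverse ddG falls outside
[-2, 2] kcal/mol — the modeled mutant is too uncertain there. The window is
exclusive: only reverse ddG < -2.0 or > 2.0 is dropped; exactly +/-2.0 kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structure_io import MultiMutation, MutationSpec, parse_multi

__all__ = ["StabilityRecord", "DatasetSplit", "REVERSE_DDG_WINDOW",
           "classify_sign", "reverse_record", "augment_reverses",
           "filter_multi", "split", "read_records_csv", "write_records_csv"]

REVERSE_DDG_WINDOW = 2.0  # kcal/mol, inclusive on both ends


@dataclass(frozen=True)
class StabilityRecord:
    structure_ref: str
    mutation: MultiMutation
    ddg: float  # kcal/mol; negative = destabilizing
    is_reverse: bool = False
    group_key: str = ""

    def __post_init__(self):
        if not math.isfinite(self.ddg):
            raise ValueError("ddG must be finite")
        if not self.group_key:
            object.__setattr__(self, "group_key", self.structure_ref)

    @property
    def is_single(self) -> bool:
        return len(self.mutation) == 1


@dataclass
class DatasetSplit:
    train: list[StabilityRecord]
    test: list[StabilityRecord]


def classify_sign(ddg: float) -> str:
    """stabilizing (ddG > 0) vs destabilizing (ddG < 0); 0 -> destabilizing."""
    if not math.isfinite(ddg):
        raise ValueError("ddG must be finite")
    return "stabilizing" if ddg > 0.0 else "destabilizing"


def reverse_record(record: StabilityRecord) -> StabilityRecord:
    """The hypothetical reverse of a single-point record: mut -> wt, -ddG."""
    (spec,) = record.mutation.specs
    rev_spec = MutationSpec(chain=spec.chain, wt=spec.mut, position=spec.position,
                            mut=spec.wt, icode=spec.icode)
    return replace(record, mutation=MultiMutation(specs=(rev_spec,)),
                   ddg=-record.ddg, is_reverse=True)


def augment_reverses(records: Sequence[StabilityRecord]) -> list[StabilityRecord]:
    """Append hypothetical reverse mutations for single-point records.

    A reverse is kept only when its ddG (= -forward ddG) lies within
    [-2.0, +2.0] kcal/mol (inclusive). Originals are returned untouched and
    first; double augmentation is refused.
    """
    if any(r.is_reverse for r in records):
        raise ValueError("input already contains reverse records "
                         "(double augmentation)")
    out = list(records)
    for r in records:
        if not r.is_single:
            continue
        rev_ddg = -r.ddg
        if rev_ddg < -REVERSE_DDG_WINDOW or rev_ddg > REVERSE_DDG_WINDOW:
            continue
        out.append(reverse_record(r))
    return out


def filter_multi(records: Iterable[StabilityRecord]) -> list[StabilityRecord]:
    """Keep double and triple mutants only."""
    return [r for r in records if len(r.mutation) in (2, 3)]


def split(records: Sequence[StabilityRecord], mode: str = "random",
          test_fraction: float = 0.2, seed: int = 0) -> DatasetSplit:
    """Train/test split.

    ``random``: uniform without replacement. ``grouped``: whole group_keys are
    assigned to the test side greedily (shuffled key order) until the fraction
    is reached — no key ever straddles the split.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(records)
    n_test = max(1, round(n * test_fraction))
    if mode == "random":
        idx = rng.permutation(n)
        test_idx = set(idx[:n_test].tolist())
        return DatasetSplit(
            train=[r for i, r in enumerate(records) if i not in test_idx],
            test=[r for i, r in enumerate(records) if i in test_idx])
    if mode == "grouped":
        keys = sorted({r.group_key for r in records})
        if len(keys) < 2:
            raise ValueError("grouped split needs at least two group keys")
        order = rng.permutation(len(keys))
        test_keys: set[str] = set()
        count = 0
        for k in order:
            if count >= n_test:
                break
            test_keys.add(keys[k])
            count += sum(1 for r in records if r.group_key == keys[k])
        if len(test_keys) == len(keys):  # keep at least one key in train
            test_keys.discard(keys[order[-1]])
        return DatasetSplit(
            train=[r for r in records if r.group_key not in test_keys],
            test=[r for r in records if r.group_key in test_keys])
    raise ValueError(f"unknown split mode {mode!r}")


# ---------------------------------------------------------------------------
# CSV interface: columns [pdb, chain, mutations, ddg, group]

def read_records_csv(path_or_buf, sign_convention: str = "neg-destab"
                     ) -> list[StabilityRecord]:
    """Read stability records; mutation grammar is validated on the way in.

    ``sign_convention``: ``neg-destab`` (package convention, default) or
    ``pos-destab`` (values are negated on read).
    """
    if sign_convention not in ("neg-destab", "pos-destab"):
        raise ValueError("sign_convention must be neg-destab or pos-destab")
    df = pd.read_csv(path_or_buf, dtype={"pdb": str, "chain": str,
                                         "mutations": str})
    required = {"pdb", "chain", "mutations", "ddg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        multi = parse_multi(row.mutations, default_chain=row.chain)
        ddg = float(row.ddg)
        if sign_convention == "pos-destab":
            ddg = -ddg
        group = getattr(row, "group", "") or ""
        records.append(StabilityRecord(structure_ref=row.pdb, mutation=multi,
                                       ddg=ddg, group_key=str(group) or row.pdb))
    return records


def write_records_csv(records: Sequence[StabilityRecord], path) -> None:
    rows = [{"pdb": r.structure_ref,
             "chain": r.mutation.specs[0].chain,
             "mutations": ",".join(
                 f"{s.chain} {s.wt}{s.position}{s.icode}{s.mut}"
                 for s in r.mutation),
             "ddg": r.ddg,
             "group": r.group_key} for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)
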