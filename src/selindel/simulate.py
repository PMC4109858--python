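"""Two-lineage genome evolution simulator with known constrained truth.

An ancestral sequence is seeded with non-overlapping constrained elements
(optionally clustered); two lineages then evolve independently for half the
total divergence each.  Substitutions follow an exact HKY85 continuous-time
Markov chain realised by uniformization (so realized substitution counts
are known, not approximated); indel events arise at a configurable rate per
neutral substitution, with insertions and deletions equiprobable and
lengths from a truncated power-law (or geometric) spectrum.  Constrained
elements block indels but not substitutions — the quantity the estimators
measure is indel constraint.  Optional turnover relocates whole elements at
rate ``b`` per unit divergence, keeping the constrained amount constant.

Because every event is tracked in ancestral coordinates, the *true*
pairwise alignment of the two extant sequences is emitted directly (as
:class:`~selindel.alignio.AlignmentBlock`\\ s) along with the element truth
in both extant genomes' coordinates.  This provides the oracle against
which NIM1/NIM2 accuracy, conservativeness and turnover recovery are
validated.

Implementation notes: lineages evolve in discrete epochs (default 100 per
branch) so that turnover, indels and the constraint mask interleave
correctly; indels act on ancestral coordinates and inserted material is
inert (no secondary events are placed on insertions — a second-order effect
at the divergences simulated).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignio import AlignmentBlock, write_maf
from .divergence import hky85_rate_matrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_ancestor",
    "evolve_pair",
    "simulate",
    "simulation_grid",
    "write_truth",
]

_GAP = ord("-")
_BASE_CHARS = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults emulate a mammalian pairwise comparison: ~41% G+C, 5%
    constrained sequence in elements of mean length 200 bp, transition/
    transversion ratio 2.5, one indel event per 10 substitutions with a
    truncated power-law length spectrum (exponent 1.6, max 50 bp).
    """

    length: int = 5_000_000
    gc: float = 0.41
    alpha_true: float = 0.05
    elem_mean_len: float = 200.0
    clustering: float = 0.0
    d_total: float = 0.3
    kappa: float = 2.5
    indel_to_sub: float = 0.1
    indel_len_law: tuple = ("zipf", 1.6, 50)
    turnover_b: float = 0.0
    n_epochs: int = 100
    seed: int = 0
    block_columns: int = 2_000_000

    def __post_init__(self):
        if not (0 <= self.alpha_true < 1):
            raise ValueError("alpha_true must be in [0, 1)")
        if not (0 <= self.clustering < 1):
            raise ValueError("clustering must be in [0, 1)")
        if self.d_total < 0:
            raise ValueError("d_total must be >= 0")

    @property
    def base_freqs(self) -> np.ndarray:
        return np.array(
            [(1 - self.gc) / 2, self.gc / 2, self.gc / 2, (1 - self.gc) / 2]
        )


@dataclass
class SimTruth:
    """Ground truth of one simulated pair.

    The emitted alignment blocks *are* the true column map between the two
    extant sequences; element intervals are given in each extant genome's
    coordinates (0-based half-open).  ``mutual_bp`` counts ancestral
    positions constrained in both lineages at the end of the run (equal to
    ``alpha_true_bp`` when turnover is off).
    """

    elements_ref: np.ndarray
    elements_qry: np.ndarray
    ancestral_elements: np.ndarray
    alpha_true_bp: int
    mutual_bp: int
    realized_d: float
    config: SimConfig = None
    n_columns: int = 0
    inserted_bp: tuple[int, int] = (0, 0)  # per lineage (ref, qry)
    deleted_bp: tuple[int, int] = (0, 0)


# ---------------------------------------------------------------------------
# ancestor


def _sample_bases(rng: np.random.Generator, n: int, freqs: np.ndarray) -> np.ndarray:
    cum = np.cumsum(freqs)
    return np.searchsorted(cum, rng.random(n)).astype(np.uint8)


def simulate_ancestor(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """I.i.d. ancestral bases at the target G+C, plus non-overlapping
    constrained elements totalling ~alpha_true * length.

    Element lengths are geometric with mean ``elem_mean_len``.  With
    probability ``clustering`` the next element starts within one mean
    length of the previous element's end, else uniformly in free sequence.
    """
    L = cfg.length
    seq = _sample_bases(rng, L, cfg.base_freqs)
    target = cfg.alpha_true * L
    occ = np.zeros(L, dtype=bool)
    elements: list[tuple[int, int]] = []
    placed = 0
    prev_end = None
    failures = 0
    while placed < target:
        elen = min(int(rng.geometric(1.0 / cfg.elem_mean_len)), L // 10)
        start = None
        if prev_end is not None and rng.random() < cfg.clustering:
            s = prev_end + 1 + int(rng.integers(0, max(int(cfg.elem_mean_len), 1)))
            if s + elen < L and not occ[max(s - 1, 0) : s + elen + 1].any():
                start = s
        if start is None:
            for _ in range(200):
                s = int(rng.integers(0, L - elen))
                if not occ[max(s - 1, 0) : s + elen + 1].any():
                    start = s
                    break
        if start is None:
            failures += 1
            if failures > 50:
                raise ValueError(
                    "infeasible element packing: alpha_true/clustering too "
                    "high for the sequence length"
                )
            continue
        occ[start : start + elen] = True
        elements.append((start, start + elen))
        placed += elen
        prev_end = start + elen
    elements.sort()
    return seq, np.array(elements, dtype=np.int64).reshape(-1, 2)


# ---------------------------------------------------------------------------
# lineage evolution


def _ranges_to_indices(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    lens = (ends - starts).astype(np.int64)
    total = int(lens.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    offs = np.concatenate([[0], np.cumsum(lens)[:-1]])
    return np.repeat(starts, lens) + (np.arange(total) - np.repeat(offs, lens))


def _draw_indel_lengths(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    law = cfg.indel_len_law
    if law[0] == "geometric":
        return rng.geometric(1.0 / float(law[1]), size=n).astype(np.int64)
    if law[0] == "zipf":
        s, lmax = float(law[1]), int(law[2])
        k = np.arange(1, lmax + 1, dtype=float)
        p = k**-s
        p /= p.sum()
        return rng.choice(np.arange(1, lmax + 1), size=n, p=p).astype(np.int64)
    raise ValueError(f"unknown indel length law {law!r}")


@dataclass
class _Lineage:
    cur: np.ndarray  # substituted bases, ancestral coordinates
    present: np.ndarray  # bool; False = deleted
    ins_len: np.ndarray  # int32; insertion immediately before position i
    constrained: np.ndarray  # bool mask at end of branch
    elements: np.ndarray  # (m, 2) ancestral coordinates at end of branch
    sub_rate_neutral: float  # realized substitutions/site on neutral exposure


def _evolve_lineage(
    seq: np.ndarray,
    elements: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    branch_d: float,
) -> _Lineage:
    L = seq.size
    cur = seq.copy()
    present = np.ones(L, dtype=bool)
    ins_len = np.zeros(L, dtype=np.int32)
    constrained = np.zeros(L, dtype=bool)
    elems = [tuple(map(int, e)) for e in elements]
    for s, e in elems:
        constrained[s:e] = True
    constr_bp = int(constrained.sum())

    Q = hky85_rate_matrix(cfg.kappa, cfg.base_freqs)
    rates = -np.diag(Q).copy()
    rmax = float(rates.max())
    jump = Q / rates[:, None]
    np.fill_diagonal(jump, 0.0)
    jump_cum = np.cumsum(jump, axis=1)

    t_ep = branch_d / cfg.n_epochs
    present_count = L
    n_jump_neutral = 0
    exposure = 0.0
    ccs: np.ndarray | None = None  # cumsum cache of the constraint mask

    for _ in range(cfg.n_epochs):
        neutral_present = present_count - constr_bp
        exposure += neutral_present * t_ep
        if t_ep > 0:
            # --- substitutions (uniformized CTMC) ---
            n_cand = rng.poisson(L * rmax * t_ep)
            if n_cand:
                pos = rng.integers(0, L, n_cand)
                pos = pos[present[pos]]
                b = cur[pos]
                keep = rng.random(pos.size) < rates[b] / rmax
                pos, b = pos[keep], b[keep]
                if pos.size:
                    u = rng.random(pos.size)
                    new = (u[:, None] >= jump_cum[b]).sum(axis=1).astype(np.uint8)
                    n_jump_neutral += int((~constrained[pos]).sum())
                    cur[pos] = new
            # --- indels at neutral positions ---
            n_indel = rng.poisson(cfg.indel_to_sub * t_ep * max(neutral_present, 0))
            if n_indel:
                pos = _sample_neutral_present(rng, L, present, constrained, n_indel)
                if pos.size:
                    is_del = rng.random(pos.size) < 0.5
                    lens = _draw_indel_lengths(cfg, pos.size, rng)
                    ipos, ilen = pos[~is_del], lens[~is_del]
                    np.add.at(ins_len, ipos, ilen.astype(np.int32))
                    dpos, dlen = pos[is_del], lens[is_del]
                    if dpos.size:
                        if ccs is None:
                            ccs = np.concatenate([[0], np.cumsum(constrained)])
                        present_count -= _apply_deletions(
                            rng, L, present, constrained, ccs, dpos, dlen
                        )
        # --- turnover: relocate whole elements ---
        if cfg.turnover_b > 0 and t_ep > 0 and elems:
            p_flip = cfg.turnover_b * t_ep
            flips = np.flatnonzero(rng.random(len(elems)) < p_flip)
            for i in flips:
                s, e = elems[i]
                elen = e - s
                spot = _find_neutral_window(rng, L, present, constrained, ins_len, elen)
                if spot is None:
                    continue  # nowhere to go this epoch; element persists
                constrained[s:e] = False
                constrained[spot : spot + elen] = True
                elems[i] = (spot, spot + elen)
            if flips.size:
                ccs = None

    return _Lineage(
        cur=cur,
        present=present,
        ins_len=ins_len,
        constrained=constrained,
        elements=np.array(sorted(elems), dtype=np.int64).reshape(-1, 2),
        # realized substitutions per neutral site along this branch:
        # jumps / (time-averaged neutral site count), the latter being
        # exposure / branch_d
        sub_rate_neutral=n_jump_neutral * branch_d / exposure if exposure > 0 else 0.0,
    )


def _sample_neutral_present(
    rng, L, present, constrained, n: int
) -> np.ndarray:
    out = []
    need = n
    for _ in range(12):
        cand = rng.integers(0, L, int(need * 1.6) + 8)
        cand = cand[present[cand] & ~constrained[cand]]
        out.append(cand[:need])
        need -= min(need, cand.size)
        if need == 0:
            break
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def _apply_deletions(rng, L, present, constrained, ccs, dpos, dlen) -> int:
    """Delete [p, p+len) footprints that avoid constrained positions;
    footprints hitting an element are re-drawn (constraint blocks indels).
    Returns the number of positions newly deleted."""
    dend = np.minimum(dpos + dlen, L)
    for _ in range(6):
        bad = (ccs[dend] - ccs[dpos]) > 0
        if not bad.any():
            break
        npos = _sample_neutral_present(rng, L, present, constrained, int(bad.sum()))
        if npos.size < bad.sum():
            dpos, dend = dpos[~bad], dend[~bad]
            break
        dpos = dpos.copy()
        dpos[bad] = npos
        dend = np.minimum(dpos + dlen, L)
    else:
        ok = (ccs[dend] - ccs[dpos]) == 0
        dpos, dend = dpos[ok], dend[ok]
    idx = np.unique(_ranges_to_indices(dpos, dend))
    newly = int(present[idx].sum())
    present[idx] = False
    return newly


def _find_neutral_window(rng, L, present, constrained, ins_len, elen) -> int | None:
    """Ancestral window for a relocated element: unconstrained and with no
    insertions inside (insertions would break extant contiguity; previously
    deleted positions do not — the surviving bases stay adjacent)."""
    for _ in range(200):
        s = int(rng.integers(0, L - elen))
        if (
            not constrained[s : s + elen].any()
            and ins_len[s + 1 : s + elen].sum() == 0
            and present[s]
        ):
            return s
    return None


# ---------------------------------------------------------------------------
# alignment construction


def _extant_intervals(
    elems: np.ndarray, present: np.ndarray, ins_len: np.ndarray
) -> np.ndarray:
    pres_cum = np.concatenate([[0], np.cumsum(present, dtype=np.int64)])
    ins_cum = np.cumsum(ins_len, dtype=np.int64)
    out = np.empty_like(elems)
    for i, (s, e) in enumerate(elems):
        start = pres_cum[s] + ins_cum[s]
        # extant length counts surviving positions only (elements placed on
        # sequence carrying earlier deletions are shorter than e - s)
        out[i] = (start, start + (pres_cum[e] - pres_cum[s]))
    return out


def evolve_pair(
    ancestor: np.ndarray,
    elements: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[AlignmentBlock], SimTruth]:
    """Evolve two lineages for d_total/2 each and emit the true pairwise
    alignment of the extant sequences plus the element truth."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lin1 = _evolve_lineage(ancestor, elements, cfg, rng, cfg.d_total / 2.0)
    lin2 = _evolve_lineage(ancestor, elements, cfg, rng, cfg.d_total / 2.0)

    L = ancestor.size
    keep = lin1.present | lin2.present
    n_at = lin1.ins_len.astype(np.int64) + lin2.ins_len + keep
    base = np.concatenate([[0], np.cumsum(n_at)])
    n_cols = int(base[-1])
    ref_arr = np.full(n_cols, _GAP, dtype=np.uint8)
    qry_arr = np.full(n_cols, _GAP, dtype=np.uint8)
    anc_col = base[:-1] + lin1.ins_len + lin2.ins_len
    ref_arr[anc_col[lin1.present]] = _BASE_CHARS[lin1.cur[lin1.present]]
    qry_arr[anc_col[lin2.present]] = _BASE_CHARS[lin2.cur[lin2.present]]
    has1 = lin1.ins_len > 0
    idx1 = _ranges_to_indices(base[:-1][has1], (base[:-1] + lin1.ins_len)[has1])
    ref_arr[idx1] = _BASE_CHARS[_sample_bases(rng, idx1.size, cfg.base_freqs)]
    has2 = lin2.ins_len > 0
    idx2 = _ranges_to_indices(
        (base[:-1] + lin1.ins_len)[has2],
        (base[:-1] + lin1.ins_len + lin2.ins_len)[has2],
    )
    qry_arr[idx2] = _BASE_CHARS[_sample_bases(rng, idx2.size, cfg.base_freqs)]

    blocks = _chunk_blocks(ref_arr, qry_arr, cfg.block_columns)

    truth = SimTruth(
        elements_ref=_extant_intervals(lin1.elements, lin1.present, lin1.ins_len),
        elements_qry=_extant_intervals(lin2.elements, lin2.present, lin2.ins_len),
        ancestral_elements=np.asarray(elements, dtype=np.int64).reshape(-1, 2),
        alpha_true_bp=int((elements[:, 1] - elements[:, 0]).sum()) if len(elements) else 0,
        mutual_bp=int(
            (lin1.constrained & lin2.constrained & lin1.present & lin2.present).sum()
        ),
        realized_d=lin1.sub_rate_neutral + lin2.sub_rate_neutral,
        config=cfg,
        n_columns=n_cols,
        inserted_bp=(int(lin1.ins_len.sum()), int(lin2.ins_len.sum())),
        deleted_bp=(int(L - lin1.present.sum()), int(L - lin2.present.sum())),
    )
    return blocks, truth


def _chunk_blocks(
    ref_arr: np.ndarray, qry_arr: np.ndarray, block_columns: int
) -> list[AlignmentBlock]:
    n_cols = ref_arr.size
    ref_total = int((ref_arr != _GAP).sum())
    qry_total = int((qry_arr != _GAP).sum())
    blocks = []
    ref_off = 0
    qry_off = 0
    for i, c0 in enumerate(range(0, n_cols, block_columns)):
        c1 = min(c0 + block_columns, n_cols)
        rt = ref_arr[c0:c1]
        qt = qry_arr[c0:c1]
        blocks.append(
            AlignmentBlock(
                ref_chrom="chr1",
                ref_start=ref_off,
                ref_strand="+",
                ref_text=rt.tobytes().decode("ascii"),
                qry_chrom="chr1",
                qry_start=qry_off,
                qry_strand="+",
                qry_text=qt.tobytes().decode("ascii"),
                block_id=f"sim:{i}",
                ref_src_size=ref_total,
                qry_src_size=qry_total,
            )
        )
        ref_off += int((rt != _GAP).sum())
        qry_off += int((qt != _GAP).sum())
    return blocks


def simulate(cfg: SimConfig) -> tuple[list[AlignmentBlock], SimTruth]:
    """End-to-end: ancestor + evolution, fully determined by cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    ancestor, elements = simulate_ancestor(cfg, rng)
    return evolve_pair(ancestor, elements, cfg, rng)


# ---------------------------------------------------------------------------
# grids and output


def simulation_grid(
    base_cfg: SimConfig,
    vary: dict[str, Sequence],
    seed: int = 0,
    methods: Sequence[str] = ("NIM1", "NIM2"),
    n_bins: int = 4,
    n_boot: int = 200,
) -> pd.DataFrame:
    """Run the estimators over a parameter grid; one row per grid point
    with estimates, truth, and any per-run failure flagged."""
    import itertools

    from .nim import NeutralIndelModel

    keys = sorted(vary)
    rows = []
    for run_i, combo in enumerate(itertools.product(*(vary[k] for k in keys))):
        params = dict(zip(keys, combo))
        cfg = dataclasses.replace(base_cfg, **params, seed=int(seed) + run_i)
        row = {**params, "seed": cfg.seed, "length": cfg.length, "error": ""}
        try:
            blocks, truth = simulate(cfg)
            row["truth_bp"] = truth.mutual_bp
            row["alpha_true_bp"] = truth.alpha_true_bp
            row["realized_d"] = truth.realized_d
            model = NeutralIndelModel.from_blocks(blocks, n_bins=n_bins)
            for method in methods:
                res = model.fit(
                    method=method, n_boot=n_boot, seed=cfg.seed + 10_000,
                    **({"ci": False} if method.upper() == "NIM2" else {}),
                )
                row[f"alpha_{method.lower()}_bp"] = res.alpha_bp
                row[f"alpha_{method.lower()}_fraction"] = res.alpha_fraction
        except Exception as exc:  # flagged, not fatal: grid rows are independent
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def write_truth(
    blocks: list[AlignmentBlock], truth: SimTruth, outdir: str | Path
) -> None:
    """Write MAF (true alignment), per-genome element BEDs, and a JSON
    truth summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_maf(blocks, outdir / "alignment.maf")
    for name, ivals in (("ref", truth.elements_ref), ("qry", truth.elements_qry)):
        with open(outdir / f"elements_{name}.bed", "w") as fh:
            for s, e in ivals:
                fh.write(f"chr1\t{s}\t{e}\n")
    summary = {
        "alpha_true_bp": truth.alpha_true_bp,
        "mutual_bp": truth.mutual_bp,
        "realized_d": truth.realized_d,
        "n_columns": truth.n_columns,
        "n_elements": len(truth.ancestral_elements),
        "config": dataclasses.asdict(truth.config) if truth.config else None,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
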