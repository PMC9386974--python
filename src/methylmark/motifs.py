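"""De novo motif discovery in DMR sequences and PWM database matching.

The finder is an expectation-maximisation mixture model in the "any number
of repetitions" (two-component / TCM) spirit: every width-w window of every
sequence is independently either a motif site (prior lambda, split equally
between strands) or background (0th-order model from the input base
composition).  Found motifs are reported with an empirical E-value: the
fitted motif's log-likelihood ratio is compared against a Gumbel (extreme
value) null fitted to LLRs obtained by refitting on composition-preserving
shuffles of the input, and the tail probability is multiplied by the size
of the search (number of candidate widths x number of motifs sought).
Discovered sites are masked before the next motif is fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_EULER_GAMMA = 0.57721566490153286


@dataclass
class PWM:
    """Position probability matrix over A,C,G,T (rows) x positions (columns)."""

    name: str
    matrix: np.ndarray  # (4, w), columns sum to 1
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (A, C, G, T)")
        if self.matrix.shape[1] < 4:
            raise ValueError("PWM width must be >= 4")
        if (self.matrix < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("each PWM column must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(name=self.name + "_rc", matrix=self.matrix[::-1, ::-1].copy())


@dataclass
class MotifSite:
    seq_index: int
    offset: int
    strand: str  # '+' or '-'
    posterior: float


@dataclass
class MotifResult:
    pwm: PWM
    n_sites: int
    llr: float
    p_value: float
    e_value: float
    sites: list[MotifSite] = field(default_factory=list)


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


def extract_dmr_sequences(
    spans: list[tuple[str, int, int]], fasta_path: str | Path, flank: int = 10
) -> list[str]:
    """Uppercase genomic sequences of DMR spans extended by ``flank`` nt each side.

    Spans reaching past a chromosome edge are clipped with a logged warning;
    an unknown chromosome is an error.  Ns are preserved.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path))
    out = []
    for chrom, start, end in spans:
        if chrom not in fasta:
            raise KeyError(f"chromosome {chrom!r} absent from {fasta_path}")
        length = len(fasta[chrom])
        lo, hi = start - flank, end + flank
        if lo < 0 or hi > length:
            logger.warning("span %s:%d-%d clipped at chromosome edge", chrom, start, end)
            lo, hi = max(lo, 0), min(hi, length)
        out.append(str(fasta[chrom][lo:hi]).upper())
    return out


def _encode(sequences: list[str]) -> list[np.ndarray]:
    return [
        np.fromiter((_CODE.get(c, 4) for c in seq.upper()), dtype=np.int8, count=len(seq))
        for seq in sequences
    ]


def _windows(
    codes: list[np.ndarray], width: int, masks: list[np.ndarray] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All valid width-w windows: (codes W x w, seq index, offset)."""
    mats, seq_idx, offsets = [], [], []
    for i, arr in enumerate(codes):
        if len(arr) < width:
            continue
        view = np.lib.stride_tricks.sliding_window_view(arr, width)
        valid = (view < 4).all(axis=1)
        if masks is not None:
            mview = np.lib.stride_tricks.sliding_window_view(masks[i], width)
            valid &= ~mview.any(axis=1)
        idx = np.flatnonzero(valid)
        if len(idx):
            mats.append(view[idx])
            seq_idx.append(np.full(len(idx), i, dtype=np.int32))
            offsets.append(idx.astype(np.int32))
    if not mats:
        return (np.empty((0, width), dtype=np.int8), np.empty(0, np.int32), np.empty(0, np.int32))
    return (np.vstack(mats), np.concatenate(seq_idx), np.concatenate(offsets))


def _background_logprobs(codes: list[np.ndarray]) -> np.ndarray:
    counts = np.ones(4)  # +1 pseudocount keeps all-N corner cases finite
    for arr in codes:
        counts += np.bincount(arr[arr < 4], minlength=4)[:4]
    return np.log(counts / counts.sum())


@dataclass
class _Fit:
    theta: np.ndarray
    lam: float
    ll: float
    llr: float
    objective_trace: list[float]
    post_fwd: np.ndarray
    post_rev: np.ndarray


def _one_hot(win: np.ndarray) -> np.ndarray:
    """(W, 4w) one-hot design matrix: column 4j+b marks base b at position j."""
    W, w = win.shape
    X = np.zeros((W, 4 * w))
    flat = win.astype(np.intp) + 4 * np.arange(w)
    X[np.arange(W)[:, None], flat] = 1.0
    return X


def _em_fit(
    X: np.ndarray,
    Xr: np.ndarray | None,
    log_b: np.ndarray,
    seed_theta: np.ndarray,
    n_iter: int,
    pseudo: float = 0.01,
    tol: float = 1e-2,
) -> _Fit:
    """EM on the window mixture; returns fit with a monotone objective trace.

    ``X``/``Xr`` are one-hot window design matrices (forward and
    reverse-complement image); scores and expected counts are single BLAS
    matvecs.  Motif widths are small enough (<= ~20) that window
    probabilities stay comfortably inside float64 range, so the mixture is
    evaluated in linear space.
    """
    both_strands = Xr is not None
    W = X.shape[0]
    w = X.shape[1] // 4
    b_lin = np.exp(log_b)
    theta = seed_theta.copy()
    # start expecting on the order of tens of sites in the pool
    lam = float(np.clip(50.0 / max(W, 1), 1e-4, 0.3))
    trace: list[float] = []
    zf = zr = np.zeros(W)

    def scores_and_posteriors(theta, lam):
        logt_flat = np.log(theta).T.ravel()  # position-major: index 4j+b
        f = np.exp(X @ logt_flat)
        fr = np.exp(Xr @ logt_flat) if both_strands else None
        if both_strands:
            denom = (lam / 2) * f + (lam / 2) * fr + (1 - lam) * b_lin
            zf = (lam / 2) * f / denom
            zr = (lam / 2) * fr / denom
        else:
            denom = lam * f + (1 - lam) * b_lin
            zf = lam * f / denom
            zr = np.zeros(W)
        return float(np.log(denom).sum()), zf, zr

    prev_obj = -np.inf
    for _ in range(n_iter):
        ll, zf, zr = scores_and_posteriors(theta, lam)
        obj = ll + float(pseudo * np.log(theta).sum())
        trace.append(obj)
        counts_flat = X.T @ zf
        if both_strands:
            counts_flat += Xr.T @ zr
        counts = counts_flat.reshape(w, 4).T + pseudo
        theta = counts / counts.sum(axis=0, keepdims=True)
        lam = float(np.clip((zf + zr).sum() / W, 1e-6, 0.5))
        if obj - prev_obj < tol and np.isfinite(prev_obj):
            break
        prev_obj = obj
    ll, zf, zr = scores_and_posteriors(theta, lam)
    trace.append(ll + float(pseudo * np.log(theta).sum()))
    return _Fit(
        theta=theta,
        lam=lam,
        ll=ll,
        llr=ll - float(log_b.sum()),
        objective_trace=trace,
        post_fwd=zf,
        post_rev=zr,
    )


def _seed_thetas(
    win: np.ndarray, n_starts: int, both_strands: bool, rng: np.random.Generator
) -> list[np.ndarray]:
    """Initial PWMs from the most frequent (strand-canonical) w-mers."""
    w = win.shape[1]
    if len(win) == 0:
        return []
    fwd = win.astype(np.int64)
    keys = fwd @ (4 ** np.arange(w - 1, -1, -1, dtype=np.int64))
    if both_strands:
        rc = (3 - fwd)[:, ::-1]
        rc_keys = rc @ (4 ** np.arange(w - 1, -1, -1, dtype=np.int64))
        keys = np.minimum(keys, rc_keys)
    uniq, counts = np.unique(keys, return_counts=True)
    top = uniq[np.argsort(-counts, kind="stable")][:n_starts]
    seeds = []
    for key in top:
        digits = []
        k = int(key)
        for _ in range(w):
            digits.append(k % 4)
            k //= 4
        digits = digits[::-1]
        theta = np.full((4, w), 0.1)
        theta[digits, np.arange(w)] = 0.7
        seeds.append(theta / theta.sum(axis=0, keepdims=True))
    return seeds


def _fit_best(
    win: np.ndarray,
    log_bg: np.ndarray,
    both_strands: bool,
    rng: np.random.Generator,
    n_starts: int,
    n_iter: int,
) -> _Fit | None:
    seeds = _seed_thetas(win, n_starts, both_strands, rng)
    if not seeds:
        return None
    w = win.shape[1]
    X = _one_hot(win)
    Xr = _one_hot((3 - win)[:, ::-1]) if both_strands else None
    log_b = X @ np.tile(log_bg, w)  # 0th-order background score per window
    best: _Fit | None = None
    for theta0 in seeds:
        fit = _em_fit(X, Xr, log_b, theta0, n_iter)
        if best is None or fit.ll > best.ll:
            best = fit
    return best


def _gumbel_tail_p(x: float, null_sample: np.ndarray) -> float:
    """Upper-tail probability of x under a moment-fitted Gumbel null."""
    mu_hat = float(np.mean(null_sample))
    sd_hat = float(np.std(null_sample, ddof=1))
    if sd_hat <= 0:
        return 1.0 if x <= mu_hat else 0.0
    beta = sd_hat * np.sqrt(6.0) / np.pi
    mode = mu_hat - _EULER_GAMMA * beta
    t = (x - mode) / beta
    if t > 700:
        return 0.0
    return float(-np.expm1(-np.exp(-t)))


def discover_motifs(
    sequences: list[str],
    widths: range | list[int] = range(6, 13),
    n_motifs: int = 20,
    both_strands: bool = True,
    seed: int = 0,
    n_null: int = 30,
    n_starts: int = 3,
    n_iter: int = 40,
) -> list[MotifResult]:
    """EM motif discovery on both strands, any number of sites per sequence.

    Up to ``n_motifs`` motifs are reported; after each accepted motif its
    sites are masked.  The per-width null LLR distribution comes from
    ``n_null`` refits on per-sequence shuffles; fixed ``seed`` makes runs
    bitwise reproducible.
    """
    widths = list(widths)
    if len(sequences) < 10:
        raise ValueError("need at least 10 sequences")
    if max(len(s) for s in sequences) < max(widths):
        raise ValueError("sequences shorter than the largest motif width")
    codes = _encode(sequences)
    if all((arr >= 4).all() for arr in codes):
        raise ValueError("input is all-N")
    log_bg = _background_logprobs(codes)
    rng = np.random.default_rng(seed)

    null_llrs: dict[int, np.ndarray] = {}
    for w in widths:
        vals = []
        for _ in range(n_null):
            shuffled = [rng.permutation(arr) for arr in codes]
            win, _, _ = _windows(shuffled, w)
            if len(win) == 0:
                vals.append(0.0)
                continue
            fit = _fit_best(win, log_bg, both_strands, rng, n_starts, n_iter)
            vals.append(fit.llr if fit else 0.0)
        null_llrs[w] = np.array(vals)

    masks = [np.zeros(len(arr), dtype=bool) for arr in codes]
    search_size = len(widths) * n_motifs
    results: list[MotifResult] = []
    for m in range(n_motifs):
        best: tuple[float, float, int, _Fit, np.ndarray, np.ndarray] | None = None
        for w in widths:
            win, seq_idx, offsets = _windows(codes, w, masks)
            if len(win) < 2:
                continue
            fit = _fit_best(win, log_bg, both_strands, rng, n_starts, n_iter)
            if fit is None:
                continue
            p = _gumbel_tail_p(fit.llr, null_llrs[w])
            cand = (p, -fit.llr, w, fit, seq_idx, offsets)
            if best is None or cand[:2] < best[:2]:
                best = cand
        if best is None:
            break
        p, _, w, fit, seq_idx, offsets = best
        post = fit.post_fwd + fit.post_rev
        site_idx = np.flatnonzero(post > 0.5)
        sites = [
            MotifSite(
                seq_index=int(seq_idx[i]),
                offset=int(offsets[i]),
                strand="+" if fit.post_fwd[i] >= fit.post_rev[i] else "-",
                posterior=float(post[i]),
            )
            for i in site_idx
        ]
        results.append(
            MotifResult(
                pwm=PWM(name=f"motif_{m + 1}_w{w}", matrix=fit.theta),
                n_sites=len(sites),
                llr=fit.llr,
                p_value=p,
                e_value=p * search_size,
                sites=sites,
            )
        )
        if not sites:
            break
        for s in sites:
            masks[s.seq_index][s.offset : s.offset + w] = True
    return results


def filter_low_complexity(
    results: list[MotifResult],
    max_e: float = 0.05,
    mono_fraction: float = 0.7,
    dinucleotide_fraction: float = 0.8,
) -> list[MotifResult]:
    """Drop low-complexity motifs (poly-base, period-2 repeats) and E >= max_e."""
    kept = []
    for r in results:
        cons = r.pwm.consensus
        w = len(cons)
        mono = max(cons.count(b) for b in BASES) / w
        if mono > mono_fraction:
            continue
        if w > 2:
            period2 = sum(cons[j] == cons[j + 2] for j in range(w - 2)) / (w - 2)
            if period2 > dinucleotide_fraction:
                continue
        if r.e_value >= max_e:
            continue
        kept.append(r)
    return kept


def _column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _best_alignment_score(query: np.ndarray, target: np.ndarray, min_overlap: int = 4) -> float:
    wq, wt = query.shape[1], target.shape[1]
    best = -np.inf
    for offset in range(-(wq - min_overlap), wt - min_overlap + 1):
        q_lo, q_hi = max(0, -offset), min(wq, wt - offset)
        if q_hi - q_lo < min_overlap:
            continue
        cols = [
            _column_correlation(query[:, j], target[:, j + offset])
            for j in range(q_lo, q_hi)
        ]
        best = max(best, float(np.mean(cols)))
    return best


def match_pwm(
    query: PWM, database: list[PWM], n_shuffles: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Rank database PWMs by similarity to the query.

    The score is the best mean column Pearson correlation over all ungapped
    offset alignments and both orientations; the empirical p-value comes
    from column-shuffled versions of the query (seeded).
    """
    if not database:
        raise ValueError("empty PWM database")
    rng = np.random.default_rng(seed)
    q_fwd = query.matrix
    q_rev = query.reverse_complement().matrix
    rows = []
    shuffles = [q_fwd[:, rng.permutation(q_fwd.shape[1])] for _ in range(n_shuffles)]
    for entry in database:
        score = max(
            _best_alignment_score(q_fwd, entry.matrix),
            _best_alignment_score(q_rev, entry.matrix),
        )
        null = np.array(
            [
                max(
                    _best_alignment_score(s, entry.matrix),
                    _best_alignment_score(s[::-1, ::-1], entry.matrix),
                )
                for s in shuffles
            ]
        )
        p = float((1 + (null >= score).sum()) / (n_shuffles + 1))
        rows.append({"target": entry.name, "score": score, "p_value": p})
    df = pd.DataFrame(rows).sort_values(
        ["score", "target"], ascending=[False, True], kind="mergesort"
    )
    return df.reset_index(drop=True)


def read_pwm_database(path: str | Path, pseudocount: float = 0.25) -> list[PWM]:
    """Read a JASPAR-style PWM text database (4 count rows per motif)."""
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows, name
        if name is not None and len(rows) == 4:
            counts = np.array(rows, dtype=float)
            probs = (counts + pseudocount) / (counts + pseudocount).sum(axis=0, keepdims=True)
            pwms.append(PWM(name=name, matrix=probs, counts=counts))
        rows, name = [], name

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                rows = []
            else:
                cleaned = line
                for ch in "ACGTacgt[]":
                    cleaned = cleaned.replace(ch, " ")
                values = [float(x) for x in cleaned.split()]
                if values:
                    rows.append(values)
    flush()
    if not pwms:
        raise ValueError(f"no PWMs parsed from {path}")
    return pwms


def write_pwm_database(pwms: list[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.name}\n")
            counts = p.counts if p.counts is not None else np.round(p.matrix * 100)
            for base, row in zip(BASES, counts):
                joined = " ".join(str(int(v)) for v in row)
                fh.write(f"{base} [ {joined} ]\n")


def write_meme_format(results: list[MotifResult], path: str | Path, background=None) -> None:
    """Write discovered motifs in MEME minimal text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if background is not None:
            freqs = " ".join(f"{b} {f:.4f}" for b, f in zip(BASES, background))
            fh.write(f"Background letter frequencies\n{freqs}\n\n")
        for r in results:
            fh.write(f"MOTIF {r.pwm.name} {r.pwm.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {r.pwm.width} "
                f"nsites= {r.n_sites} E= {r.e_value:.3g}\n"
            )
            for j in range(r.pwm.width):
                fh.write(" ".join(f"{r.pwm.matrix[i, j]:.6f}" for i in range(4)) + "\n")
            fh.write("\n")
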