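"""Synthetic longitudinal corpora with the structure the analysis assumes.

The generator emulates, at desk scale, a population of social-media
users in which (i) treatment disclosure is confounded with observable
covariates (followers, activity, tenure, baseline symptom rate),
(ii) treated users improve heterogeneously after disclosure (per-user
improvement effect delta drawn from a normal distribution), and
(iii) users in the most/least-improved halves of the delta distribution
emit distinct planted side-effect phrases in their posttreatment posts.
Symptomatic state is materialized as dedicated marker tokens consumed
by the outcome scorer, decoupling text realism from statistical
structure. All randomness flows from one generator stream in a fixed,
documented order, so a seed fully determines the corpus.

Corpus files are JSON-lines (one post per line). Two TSV sidecars
accompany them: ``<stem>.users.tsv`` with observable profile metadata
(follower counts), and ``<stem>.truth.tsv`` with the hidden
ground-truth record per user (treatment status, delta, baseline rate)
that the analysis pipeline never reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GenerationError, ParseError, ValidationError
from .outcomes import OUTCOMES, load_scorer_config

# epoch seconds for the default 4-year observation window
DEFAULT_WINDOW_START = 1388534400  # 2014-01-01T00:00:00Z
DEFAULT_WINDOW_END = 1518652800    # 2018-02-15T00:00:00Z

DEFAULT_DRUGS = ("sertraline", "escitalopram", "fluoxetine", "duloxetine")

DEFAULT_PLANTED_IMPROVED = (
    "fall asleep",
    "weight loss",
    "feeling better",
    "hours sleep",
    "lose weight",
)
DEFAULT_PLANTED_WORSENED = (
    "weight gain",
    "want eat",
    "sleep paralysis",
    "panic attack",
    "chronic pain",
)

CONFOUNDER_NAMES = ("log_followers", "log_activity", "tenure_days", "baseline_rate")


@dataclass(frozen=True)
class Post:
    post_id: str
    user_id: str
    timestamp: int
    text: str


@dataclass
class UserTimeline:
    """One user's ordered posts plus treatment metadata.

    ``truth`` holds the hidden generation record (covariates, delta,
    baseline rate) used only by recovery tests, never by the pipeline.
    """

    user_id: str
    posts: list
    n_followers: int = 0
    is_treatment: bool = False
    drug: str | None = None
    disclosure_time: int | None = None
    truth: dict | None = None

    def __post_init__(self):
        self.posts = sorted(self.posts, key=lambda p: (p.timestamp, p.post_id))
        has_t = self.disclosure_time is not None
        if self.is_treatment != has_t or self.is_treatment != (self.drug is not None):
            raise ValidationError(
                f"user {self.user_id!r}: is_treatment, drug and "
                "disclosure_time must be jointly present or absent"
            )


@dataclass
class SimConfig:
    """Study conditions for one synthetic corpus."""

    n_treatment: int = 1000
    n_control: int = 1000
    posts_per_user_mean: float = 70.0
    vocab_size: int = 500
    confounder_coefs: tuple = (1.5, 0.6, 0.0, -0.5)  # over CONFOUNDER_NAMES, standardized
    baseline_symptom_alpha: float = 3.0
    baseline_symptom_beta: float = 7.0
    improvement_effect_mean: float = 0.10
    improvement_effect_sd: float = 0.10
    # correlation between a treated user's improvement effect and their
    # baseline symptom rate: negative by default (severe baseline cases
    # respond less, in both absolute and relative terms), which is what
    # lets a ratio-based effect measure distinguish improvement strata.
    # The marginal of delta stays Normal(mean, sd).
    improvement_baseline_corr: float = -0.8
    inject_rate_improved: float = 0.3
    inject_rate_worsened: float = 0.3
    planted_terms_improved: tuple = DEFAULT_PLANTED_IMPROVED
    planted_terms_worsened: tuple = DEFAULT_PLANTED_WORSENED
    window_start: int = DEFAULT_WINDOW_START
    window_end: int = DEFAULT_WINDOW_END
    seed: int = 0
    drugs: tuple = DEFAULT_DRUGS
    min_posts: int = 5
    mention_only_rate: float = 0.05
    marker_terms: dict | None = None  # outcome -> token; default from scorer config

    def validate(self) -> None:
        if self.n_treatment <= 0 or self.n_control <= 0:
            raise ValidationError("n_treatment and n_control must be positive")
        if self.posts_per_user_mean <= 0:
            raise ValidationError("posts_per_user_mean must be positive")
        for name in ("inject_rate_improved", "inject_rate_worsened", "mention_only_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not self.window_start < self.window_end:
            raise ValidationError("window_start must precede window_end")
        n_planted = len(self.planted_terms_improved) + len(self.planted_terms_worsened)
        if self.vocab_size < n_planted + 10:
            raise ValidationError(
                f"vocab_size must be >= planted terms + 10 ({n_planted + 10})"
            )
        if len(self.confounder_coefs) != len(CONFOUNDER_NAMES):
            raise ValidationError(
                f"confounder_coefs must have {len(CONFOUNDER_NAMES)} entries"
            )
        if self.baseline_symptom_alpha <= 0 or self.baseline_symptom_beta <= 0:
            raise ValidationError("Beta prior parameters must be positive")

    def resolved_markers(self) -> dict:
        if self.marker_terms is not None:
            return dict(self.marker_terms)
        return {out: terms[0] for out, terms in load_scorer_config().items()}


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - x.mean(axis=0)) / sd


def _select_treated(rng, p: np.ndarray, n_treatment: int) -> np.ndarray:
    """Exact-quota treated selection: weighted sampling without replacement.

    Gumbel-max keys on log acceptance probabilities reproduce sequential
    probability-proportional sampling with exact quotas (the spec's
    'assign then quota-resample' step without a rejection loop).
    """
    feasible = int((p > 1e-12).sum())
    if feasible < n_treatment:
        raise GenerationError(
            f"only {feasible} users have non-negligible acceptance "
            f"probability; cannot fill treatment quota {n_treatment}"
        )
    with np.errstate(divide="ignore"):
        keys = np.log(p) + rng.gumbel(size=p.shape[0])
    treated = np.argsort(-keys, kind="stable")[:n_treatment]
    return np.sort(treated)


def _zipf_weights(v: int) -> np.ndarray:
    w = 1.0 / np.arange(1, v + 1)
    return w / w.sum()


def generate_population(config: SimConfig) -> list:
    """Generate ``n_treatment + n_control`` user timelines.

    Draw order (single stream): covariates, treatment selection keys,
    improvement effects, drug/disclosure assignment, then per-user post
    counts, timestamps and token draws in user-id order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_treatment + config.n_control

    # 1. covariates
    n_followers = np.floor(rng.lognormal(mean=5.0, sigma=1.2, size=n)).astype(int) + 1
    extra = rng.negative_binomial(5, 5.0 / (5.0 + max(config.posts_per_user_mean - config.min_posts, 1e-9)), size=n)
    n_posts = config.min_posts + extra
    tenure = rng.uniform(200.0, 1400.0, size=n)
    baseline = rng.beta(config.baseline_symptom_alpha, config.baseline_symptom_beta, size=n)

    X = np.column_stack([np.log(n_followers), np.log(n_posts), tenure, baseline])
    gamma = np.asarray(config.confounder_coefs, dtype=float)
    logits = _standardize(X) @ gamma
    p_treat = 1.0 / (1.0 + np.exp(-logits))

    # 2. treatment quota
    treated_idx = _select_treated(rng, p_treat, config.n_treatment)
    is_treated = np.zeros(n, dtype=bool)
    is_treated[treated_idx] = True

    # 3. improvement effects (controls have delta = 0); among treated,
    # delta correlates with standardized baseline severity
    delta = np.zeros(n)
    rho = float(config.improvement_baseline_corr)
    b_t = baseline[treated_idx]
    b_sd = b_t.std(ddof=0)
    z_b = (b_t - b_t.mean()) / b_sd if b_sd > 0 else np.zeros_like(b_t)
    eps = rng.standard_normal(config.n_treatment)
    delta[treated_idx] = config.improvement_effect_mean + config.improvement_effect_sd * (
        rho * z_b + np.sqrt(max(1.0 - rho * rho, 0.0)) * eps
    )
    treated_median = float(np.median(delta[treated_idx]))
    improved = np.zeros(n, dtype=bool)
    improved[treated_idx] = delta[treated_idx] > treated_median

    # 4. drug and disclosure time per treated user
    drugs = rng.choice(np.asarray(config.drugs, dtype=object), size=config.n_treatment)
    span = config.window_end - config.window_start
    lo = config.window_start + int(0.25 * span)
    hi = config.window_start + int(0.75 * span)
    disclose = rng.integers(lo, hi, size=config.n_treatment)

    markers = config.resolved_markers()
    vocab = np.array([f"w{i:04d}" for i in range(config.vocab_size)], dtype=object)
    weights = _zipf_weights(config.vocab_size)
    planted_imp = [t.split() for t in config.planted_terms_improved]
    planted_wor = [t.split() for t in config.planted_terms_worsened]

    timelines = []
    t_rank = {int(g): k for k, g in enumerate(treated_idx)}
    for i in range(n):
        user_id = f"u{i:05d}"
        treated = bool(is_treated[i])
        b = float(np.clip(baseline[i], 0.01, 0.99))
        q_post = float(np.clip(baseline[i] - delta[i], 0.01, 0.99))
        t0 = int(disclose[t_rank[i]]) if treated else None

        timestamps = np.sort(
            rng.integers(config.window_start, config.window_end, size=int(n_posts[i]))
        )
        lengths = 4 + rng.poisson(5.0, size=int(n_posts[i]))

        posts = []
        for k, ts in enumerate(timestamps):
            toks = list(rng.choice(vocab, size=int(lengths[k]), p=weights))
            post_window = treated and ts > t0
            q = q_post if post_window else b
            for out in OUTCOMES:
                if rng.random() < q:
                    toks.append(markers[out])
            if post_window:
                group = planted_imp if improved[i] else planted_wor
                rate = (
                    config.inject_rate_improved
                    if improved[i]
                    else config.inject_rate_worsened
                )
                if group and rng.random() < rate:
                    toks.extend(group[int(rng.integers(len(group)))])
            posts.append(
                Post(
                    post_id=f"{user_id}-{k:04d}",
                    user_id=user_id,
                    timestamp=int(ts),
                    text=" ".join(toks),
                )
            )

        if treated:
            drug = str(drugs[t_rank[i]])
            posts.append(
                Post(
                    post_id=f"{user_id}-disc",
                    user_id=user_id,
                    timestamp=t0,
                    text=f"i took {drug} today",
                )
            )
        else:
            drug = None
            if config.mention_only_rate > 0 and rng.random() < config.mention_only_rate:
                m_drug = str(config.drugs[int(rng.integers(len(config.drugs)))])
                ts = int(rng.integers(config.window_start, config.window_end))
                posts.append(
                    Post(
                        post_id=f"{user_id}-ment",
                        user_id=user_id,
                        timestamp=ts,
                        text=f"my friend takes {m_drug} and read about {m_drug} in the news",
                    )
                )

        truth = {
            "is_treatment": treated,
            "drug": drug,
            "disclosure_time": t0,
            "delta": float(delta[i]),
            "baseline_rate": b,
            "q_post": q_post,
            "improved": bool(improved[i]),
            "log_followers": float(np.log(n_followers[i])),
            "log_activity": float(np.log(n_posts[i])),
            "tenure_days": float(tenure[i]),
            "p_treat": float(p_treat[i]),
        }
        timelines.append(
            UserTimeline(
                user_id=user_id,
                posts=posts,
                n_followers=int(n_followers[i]),
                is_treatment=treated,
                drug=drug,
                disclosure_time=t0,
                truth=truth,
            )
        )
    return timelines


# ---------------------------------------------------------------------------
# corpus I/O

_TRUTH_COLS = (
    "user_id", "is_treatment", "drug", "disclosure_time", "delta",
    "baseline_rate", "q_post", "improved", "log_followers", "log_activity",
    "tenure_days", "p_treat",
)


def _sidecar_paths(path: Path) -> tuple:
    stem = path.with_suffix("")
    return Path(f"{stem}.users.tsv"), Path(f"{stem}.truth.tsv")


def write_corpus(timelines: Sequence[UserTimeline], path) -> Path:
    """Write posts as JSON-lines plus users/truth TSV sidecars."""
    path = Path(path)
    users_path, truth_path = _sidecar_paths(path)
    with path.open("w", encoding="utf-8") as fh:
        for tl in timelines:
            for post in tl.posts:
                fh.write(
                    json.dumps(
                        {
                            "user_id": post.user_id,
                            "post_id": post.post_id,
                            "timestamp": post.timestamp,
                            "text": post.text,
                        },
                        sort_keys=True,
                        separators=(",", ":"),
                    )
                    + "\n"
                )
    with users_path.open("w", encoding="utf-8") as fh:
        fh.write("user_id\tn_followers\n")
        for tl in timelines:
            fh.write(f"{tl.user_id}\t{tl.n_followers}\n")
    with truth_path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_TRUTH_COLS) + "\n")
        for tl in timelines:
            row = dict(tl.truth or {}, user_id=tl.user_id)
            fh.write(
                "\t".join(_format_truth(row.get(c)) for c in _TRUTH_COLS) + "\n"
            )
    return path


def _format_truth(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _parse_truth_row(header, fields) -> dict:
    row = dict(zip(header, fields))
    out = {"user_id": row["user_id"]}
    out["is_treatment"] = row["is_treatment"] == "1"
    out["drug"] = row["drug"] or None
    out["disclosure_time"] = int(row["disclosure_time"]) if row["disclosure_time"] else None
    for k in ("delta", "baseline_rate", "q_post", "log_followers", "log_activity", "tenure_days", "p_treat"):
        out[k] = float(row[k])
    out["improved"] = row["improved"] == "1"
    return out


def read_corpus(path, with_truth: bool = True) -> list:
    """Read a JSON-lines corpus back into timelines.

    With ``with_truth=False`` (the analysis pipeline's mode) treatment
    metadata and the hidden truth block are left unset; only posts and
    observable profile metadata are loaded.
    """
    path = Path(path)
    users_path, truth_path = _sidecar_paths(path)

    posts_by_user: dict = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                post = Post(
                    post_id=str(rec["post_id"]),
                    user_id=str(rec["user_id"]),
                    timestamp=int(rec["timestamp"]),
                    text=str(rec["text"]),
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ParseError(f"{path}: malformed line {lineno}: {exc}") from exc
            posts_by_user.setdefault(post.user_id, []).append(post)

    followers: dict = {}
    if users_path.exists():
        lines = users_path.read_text(encoding="utf-8").splitlines()
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            try:
                uid, nf = line.split("\t")
                followers[uid] = int(nf)
            except ValueError as exc:
                raise ParseError(f"{users_path}: malformed line {lineno}: {exc}") from exc

    truths: dict = {}
    if with_truth and truth_path.exists():
        lines = truth_path.read_text(encoding="utf-8").splitlines()
        header = lines[0].split("\t") if lines else []
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            try:
                t = _parse_truth_row(header, line.split("\t"))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{truth_path}: malformed line {lineno}: {exc}") from exc
            truths[t.pop("user_id")] = t

    user_ids = sorted(set(posts_by_user) | set(truths))
    timelines = []
    for uid in user_ids:
        t = truths.get(uid)
        timelines.append(
            UserTimeline(
                user_id=uid,
                posts=posts_by_user.get(uid, []),
                n_followers=followers.get(uid, 0),
                is_treatment=bool(t["is_treatment"]) if t else False,
                drug=t["drug"] if t else None,
                disclosure_time=t["disclosure_time"] if t else None,
                truth=t,
            )
        )
    return timelines
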