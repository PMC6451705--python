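"""End-to-end orchestration and command-line interface.

``run_pipeline`` drives corpus -> per-condition profiles -> filtered /
standardized correlation analyses (pairwise Pearson and per-facet CCA) ->
rankings and quartile summaries -> per-condition interaction networks, writing
every artifact as CSV/TSV/GraphML plus a ``run_manifest.json`` capturing all
parameters, library versions and the seed, so every numeric artifact is
regenerable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import tomllib
from dataclasses import dataclass
from importlib.metadata import version as _pkg_version
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import facet_correlation as fc
from . import interaction_network as inet
from .community_profile import profile_community, profiles_to_frame, read_profiles, \
    write_profiles
from .synthetic_data import SimulationConfig, simulate_dataset
from .tweet_io import assign_conditions, read_condition_map, read_tweets

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "cli", "main"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage (and condition)."""


@dataclass
class RunConfig:
    """Fully-specified parameter set of one pipeline run."""

    tweets_path: str
    condition_map_path: str
    out_dir: str
    min_tweets: int = 100
    min_users: int = 50
    iqr_mode: str = "tukey"
    retweet_share_mode: str = "originals"
    ridge: float = 1e-8
    n_permutations: int = 999
    seed: int = 0
    hub_threshold: float = 0.5
    network_top: int = 12
    rank_k: int = 20


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def _cca_frame(res: fc.CCAResult, facets: dict[str, str]) -> pd.DataFrame:
    rows = []
    for var in res.weights_x.index:
        rows.append({"variable": var, "facet": facets.get(var, "x"),
                     "weight": res.weights_x[var], "loading": res.loadings_x[var]})
    for var in res.weights_y.index:
        rows.append({"variable": var, "facet": "engagement",
                     "weight": res.weights_y[var], "loading": res.loadings_y[var]})
    return pd.DataFrame(rows, columns=["variable", "facet", "weight", "loading"])


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cmap = _stage("read_condition_map", read_condition_map, config.condition_map_path)
    tweets = _stage("read_tweets", lambda p: list(read_tweets(p, strict=False)),
                    config.tweets_path)
    corpora, dropped = _stage("assign_conditions", assign_conditions, tweets, cmap)
    if not corpora:
        raise PipelineError("stage 'assign_conditions' failed: no tweets matched any condition")

    profiles = []
    for corpus in corpora:
        try:
            profiles.append(profile_community(
                corpus, iqr_mode=config.iqr_mode,
                retweet_share_mode=config.retweet_share_mode))
        except Exception as exc:
            raise PipelineError(
                f"stage 'profile' failed for condition {corpus.condition!r}: {exc}") from exc
    prof_df = profiles_to_frame(profiles)
    write_profiles(prof_df, out / "profiles.csv")

    kept = _stage("filter", fc.filter_communities, prof_df,
                  config.min_tweets, config.min_users)
    empty_corr = pd.DataFrame(columns=["engagement_var", "other_var", "facet", "r", "n"])
    empty_cca = pd.DataFrame(columns=["variable", "facet", "weight", "loading"])
    if len(kept) < 3:
        # too few communities for any correlation estimate; keep artifact shape
        logger.warning("only %d retained communities; correlation analyses skipped",
                       len(kept))
        empty_corr.to_csv(out / "pairwise.csv", index=False)
        for facet in ("content", "user"):
            empty_cca.to_csv(out / f"cca_{facet}.csv", index=False)
        pd.DataFrame(columns=["facet_pair", "r", "n_communities", "facet"]).to_csv(
            out / "cca_summary.csv", index=False)
    else:
        z = _stage("standardize", lambda: fc.standardize(fc.drop_totals(kept)))
        pairwise = _stage("pairwise", fc.pairwise_engagement_correlation,
                          fc.ProfileMatrix(z))
        pairwise.to_csv(out / "pairwise.csv", index=False, float_format="%.10g")

        rng = np.random.default_rng(config.seed)
        cca_summary = []
        block_width = {"content": len(fc.CONTENT_VARS), "user": len(fc.USER_VARS)}
        for facet in ("content", "user"):
            if len(kept) <= max(block_width[facet], len(fc.ENGAGEMENT_VARS)):
                logger.warning("cca_%s skipped: %d communities <= %d variables",
                               facet, len(kept), block_width[facet])
                empty_cca.to_csv(out / f"cca_{facet}.csv", index=False)
                continue
            res, stats = _stage(f"cca_{facet}", fc.cross_facet_cca, prof_df, facet,
                                config.min_tweets, config.min_users, config.ridge,
                                config.n_permutations, rng)
            _cca_frame(res, fc.FACET_OF).to_csv(
                out / f"cca_{facet}.csv", index=False, float_format="%.10g")
            cca_summary.append({"facet_pair": f"{facet}~engagement", "r": res.r,
                                **stats})
        pd.DataFrame(cca_summary).to_csv(out / "cca_summary.csv", index=False,
                                         float_format="%.10g")

    k = min(config.rank_k, len(prof_df) // 2)
    rank_rows = []
    if k >= 1:
        for by in ("tweets", "users"):
            top, bottom = fc.rank_communities(prof_df, by=by, k=k)
            col = top.columns[-1]
            for which, frame in (("top", top), ("bottom", bottom)):
                for rank, row in enumerate(frame.itertuples(index=False), start=1):
                    rank_rows.append({"ranked_by": by, "which": which, "rank": rank,
                                      "condition": row.condition,
                                      "value": getattr(row, col)})
    pd.DataFrame(rank_rows, columns=["ranked_by", "which", "rank", "condition",
                                     "value"]).to_csv(out / "rankings.csv", index=False)

    quartiles = []
    if len(kept) >= 4:
        for var in ("pct_retweet", "pct_like", "pct_reply", "pct_quote"):
            quartiles.append(fc.quartile_engagement_summary(kept, var))
    (pd.concat(quartiles, ignore_index=True) if quartiles else pd.DataFrame()).to_csv(
        out / "quartiles.csv", index=False, float_format="%.10g")

    # network analysis on the largest communities (by total tweets)
    graph_dir = out / "graphs"
    graph_dir.mkdir(exist_ok=True)
    selected = prof_df.sort_values(["total_tweets", "total_tweets"],
                                   ascending=False).head(config.network_top)
    selected = sorted(selected.index)
    net_rows = []
    by_name = {c.condition: c for c in corpora}
    for cond in selected:
        corpus = by_name[cond]
        try:
            ig = inet.build_graph(corpus.tweets)
            part = inet.cluster_graph(ig)
            summary = inet.summarize_network(ig, part, hub_threshold=config.hub_threshold)
        except Exception as exc:
            raise PipelineError(
                f"stage 'network' failed for condition {cond!r}: {exc}") from exc
        inet.write_graphml(ig, graph_dir / f"{cond}.graphml")
        inet.write_edge_list(ig, graph_dir / f"{cond}_edges.tsv")
        inet.write_partition(part, graph_dir / f"{cond}_clusters.csv")
        n_broadcast = int(summary.cluster_table["broadcast_like"].sum()) \
            if len(summary.cluster_table) else 0
        net_rows.append({
            "condition": cond,
            "n_nodes": summary.n_nodes,
            "n_edges": summary.n_edges,
            "isolate_fraction": summary.isolate_fraction,
            "n_clusters": len(summary.cluster_sizes),
            "largest_cluster": summary.cluster_sizes[0] if summary.cluster_sizes else 0,
            "modularity": summary.q,
            "n_broadcast_like": n_broadcast,
        })
    pd.DataFrame(net_rows).to_csv(out / "network_summary.csv", index=False,
                                  float_format="%.10g")

    manifest = {
        "config": dataclasses.asdict(config),
        "n_input_tweets": len(tweets),
        "n_dropped_tweets": dropped,
        "n_conditions_profiled": len(prof_df),
        "n_conditions_retained": len(kept),
        "versions": {
            "tweetfacets": _safe_version("tweetfacets"),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": sys.version.split()[0],
        },
    }
    with (out / "run_manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def _safe_version(name: str) -> str:
    try:
        return _pkg_version(name)
    except Exception:
        return "unknown"


# ---------------------------------------------------------------- CLI


def _load_config_file(path: str | None) -> dict:
    if not path:
        return {}
    with open(path, "rb") as fh:
        return tomllib.load(fh)


@click.group()
@click.version_option(_safe_version("tweetfacets"), prog_name="tweetfacets")
def cli() -> None:
    """Multifacet profiling and correlation analysis of tweet communities."""
    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--conditions", "-n", default=200, show_default=True)
@click.option("--rho", default=0.7, show_default=True,
              help="Planted content~engagement canonical correlation.")
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "-o", "out_dir", required=True, type=click.Path())
def simulate(conditions: int, rho: float, seed: int, out_dir: str) -> None:
    """Generate a synthetic tweet corpus with known ground truth."""
    cfg = SimulationConfig(n_conditions=conditions, rho=rho, seed=seed)
    simulate_dataset(cfg, out_dir=out_dir)
    click.echo(f"wrote tweets.jsonl, condition_map.csv, truth.json to {out_dir}")


@cli.command()
@click.argument("tweets", type=click.Path(exists=True))
@click.argument("condition_map", type=click.Path(exists=True))
@click.option("--out", "-o", "out_path", required=True, type=click.Path())
@click.option("--iqr-mode", default="tukey", type=click.Choice(["tukey", "literal"]),
              show_default=True)
@click.option("--retweet-share-mode", default="originals",
              type=click.Choice(["originals", "corpus"]), show_default=True)
def profile(tweets: str, condition_map: str, out_path: str, iqr_mode: str,
            retweet_share_mode: str) -> None:
    """Compute per-condition community profiles into a CSV matrix."""
    cmap = read_condition_map(condition_map)
    corpora, _ = assign_conditions(read_tweets(tweets, strict=False), cmap)
    profs = [profile_community(c, iqr_mode=iqr_mode,
                               retweet_share_mode=retweet_share_mode) for c in corpora]
    write_profiles(profs, out_path)
    click.echo(f"wrote {len(profs)} profiles to {out_path}")


@cli.command()
@click.argument("profiles", type=click.Path())
@click.option("--out", "-o", "out_dir", required=True, type=click.Path())
@click.option("--min-tweets", default=100, show_default=True)
@click.option("--min-users", default=50, show_default=True)
@click.option("--permutations", default=999, show_default=True)
@click.option("--seed", default=0, show_default=True)
def correlate(profiles: str, out_dir: str, min_tweets: int, min_users: int,
              permutations: int, seed: int) -> None:
    """Pairwise Pearson and per-facet CCA from a profiles CSV."""
    if not Path(profiles).exists():
        raise click.ClickException(f"profiles file not found: {profiles}")
    df = read_profiles(profiles)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kept = fc.filter_communities(df, min_tweets=min_tweets, min_users=min_users)
    z = fc.standardize(fc.drop_totals(kept))
    fc.pairwise_engagement_correlation(fc.ProfileMatrix(z)).to_csv(
        out / "pairwise.csv", index=False, float_format="%.10g")
    rng = np.random.default_rng(seed)
    rows = []
    for facet in ("content", "user"):
        res, stats = fc.cross_facet_cca(df, facet, min_tweets, min_users,
                                        n_perm=permutations, rng=rng)
        _cca_frame(res, fc.FACET_OF).to_csv(out / f"cca_{facet}.csv", index=False,
                                            float_format="%.10g")
        rows.append({"facet_pair": f"{facet}~engagement", "r": res.r, **stats})
        click.echo(f"{facet}~engagement: r={res.r:.4f} "
                   f"(n={stats['n_communities']}, p={stats.get('p_value', 'n/a')})")
    pd.DataFrame(rows).to_csv(out / "cca_summary.csv", index=False, float_format="%.10g")


@cli.command()
@click.argument("tweets", type=click.Path(exists=True))
@click.argument("condition_map", type=click.Path(exists=True))
@click.option("--out", "-o", "out_dir", required=True, type=click.Path())
@click.option("--top", default=12, show_default=True,
              help="Analyse the top-N communities by total tweets.")
@click.option("--hub-threshold", default=0.5, show_default=True)
def network(tweets: str, condition_map: str, out_dir: str, top: int,
            hub_threshold: float) -> None:
    """Interaction graphs, CNM clusters and structure summaries."""
    cmap = read_condition_map(condition_map)
    corpora, _ = assign_conditions(read_tweets(tweets, strict=False), cmap)
    corpora = sorted(corpora, key=lambda c: (-len(c.tweets), c.condition))[:top]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for corpus in sorted(corpora, key=lambda c: c.condition):
        ig = inet.build_graph(corpus.tweets)
        part = inet.cluster_graph(ig)
        s = inet.summarize_network(ig, part, hub_threshold=hub_threshold)
        inet.write_graphml(ig, out / f"{corpus.condition}.graphml")
        inet.write_edge_list(ig, out / f"{corpus.condition}_edges.tsv")
        inet.write_partition(part, out / f"{corpus.condition}_clusters.csv")
        rows.append({"condition": corpus.condition, "n_nodes": s.n_nodes,
                     "n_edges": s.n_edges, "isolate_fraction": s.isolate_fraction,
                     "n_clusters": len(s.cluster_sizes), "modularity": s.q})
    pd.DataFrame(rows).to_csv(out / "network_summary.csv", index=False,
                              float_format="%.10g")
    click.echo(f"analysed {len(rows)} communities into {out_dir}")


@cli.command()
@click.argument("profiles", type=click.Path())
@click.option("--out", "-o", "out_dir", required=True, type=click.Path())
@click.option("--k", default=20, show_default=True)
def report(profiles: str, out_dir: str, k: int) -> None:
    """Rankings and engagement quartile summaries from a profiles CSV."""
    if not Path(profiles).exists():
        raise click.ClickException(f"profiles file not found: {profiles}")
    df = read_profiles(profiles)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k = min(k, len(df) // 2)
    rows = []
    for by in ("tweets", "users"):
        top, bottom = fc.rank_communities(df, by=by, k=k)
        col = top.columns[-1]
        for which, frame in (("top", top), ("bottom", bottom)):
            for rank, row in enumerate(frame.itertuples(index=False), start=1):
                rows.append({"ranked_by": by, "which": which, "rank": rank,
                             "condition": row.condition, "value": getattr(row, col)})
    pd.DataFrame(rows).to_csv(out / "rankings.csv", index=False)
    quart = [fc.quartile_engagement_summary(df, v)
             for v in ("pct_retweet", "pct_like", "pct_reply", "pct_quote")]
    pd.concat(quart, ignore_index=True).to_csv(out / "quartiles.csv", index=False,
                                               float_format="%.10g")
    click.echo(f"wrote rankings.csv and quartiles.csv to {out_dir}")


@cli.command()
@click.argument("tweets", type=click.Path(exists=True))
@click.argument("condition_map", type=click.Path(exists=True))
@click.option("--out", "-o", "out_dir", required=True, type=click.Path())
@click.option("--config", "config_file", type=click.Path(exists=True),
              help="TOML file of RunConfig keys; CLI flags override it.")
@click.option("--min-tweets", default=None, type=int)
@click.option("--min-users", default=None, type=int)
@click.option("--iqr-mode", default=None, type=click.Choice(["tukey", "literal"]))
@click.option("--retweet-share-mode", default=None,
              type=click.Choice(["originals", "corpus"]))
@click.option("--permutations", default=None, type=int)
@click.option("--seed", default=None, type=int)
@click.option("--network-top", default=None, type=int)
def run(tweets: str, condition_map: str, out_dir: str, config_file: str | None,
        **overrides) -> None:
    """Full pipeline: profiles, correlations, rankings, networks, manifest."""
    params = _load_config_file(config_file)
    rename = {"permutations": "n_permutations"}
    for key, value in overrides.items():
        if value is not None:
            params[rename.get(key, key)] = value
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(params) - allowed
    if unknown:
        raise click.ClickException(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(tweets_path=tweets, condition_map_path=condition_map,
                    out_dir=out_dir, **params)
    logger.info("run config: %s", dataclasses.asdict(cfg))
    try:
        run_pipeline(cfg)
    except PipelineError as exc:
        raise click.ClickException(str(exc)) from exc
    click.echo(f"pipeline complete: artifacts in {out_dir}")


def main() -> None:
    cli()


if __name__ == "__main__":
    main()
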