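"""Command-line interface and pentad figure rendering.

One multi-command entry point: ``cis``, ``trans`` and ``distance`` build a
pile-up and write it as JSON (plus an optional figure); ``strength`` writes
the per-chromosome strength TSV; ``compare`` runs the paired signed-rank
test between two strength tables; ``plot`` renders a stored pile-up;
``simulate`` writes synthetic fixtures.
"""

from __future__ import annotations

import logging

import click
import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LogNorm

from . import __version__
from .aggregate import Pentad, PentadSettings, build_pentad, panel_key
from .compartments import DEFAULT_DISTANCE_BINS, segment_signal
from .errors import PentadError
from .genome_io import (
    read_compartment_signal,
    read_contact_matrix,
    read_genome_bins,
    validate_inputs,
)
from .oe_transform import expected_cis, oe_cis, oe_trans
from .strength import (
    compare_conditions,
    read_strength_table,
    strength_genome,
    write_comparison,
    write_strength_table,
)
from .synthetic import SyntheticSpec, generate_genome, write_fixture

logger = logging.getLogger("pentad")


# ---------------------------------------------------------------------------
# rendering

_CIS_LAYOUT = {"A_short": (0, 0), "A_long": (0, 2), "AB": (1, 1),
               "B_long": (2, 0), "B_short": (2, 2)}
_TRANS_LAYOUT = {"A_long": (0, 0), "AB": (1, 1), "B_long": (2, 2)}


def _draw_panel(ax, values, title, norm, cmap):
    cmap = plt.get_cmap(cmap).copy()
    cmap.set_bad("#dddddd")
    if np.isfinite(values).any():
        ax.imshow(values, norm=norm, cmap=cmap, interpolation="nearest")
    else:
        ax.text(0.5, 0.5, "no data", ha="center", va="center",
                transform=ax.transAxes, fontsize=9)
    ax.set_title(title, fontsize=8)
    ax.set_xticks([])
    ax.set_yticks([])


def render_pentad(
    pentad: Pentad,
    path: str | None = None,
    vmin: float = 0.5,
    vmax: float = 2.0,
    cmap: str = "coolwarm",
):
    """Compose the five-panel (or per-stratum) average-compartment figure.

    Color scale is logarithmic and symmetric around O/E = 1 when
    vmin * vmax = 1 (the default [1/2, 2] limits).
    """
    norm = LogNorm(vmin=vmin, vmax=vmax)
    if pentad.mode in ("cis", "trans"):
        layout = _CIS_LAYOUT if pentad.mode == "cis" else _TRANS_LAYOUT
        fig, axes = plt.subplots(3, 3, figsize=(6, 6))
        for ax in axes.ravel():
            ax.set_visible(False)
        for key, (r, c) in layout.items():
            ax = axes[r, c]
            ax.set_visible(True)
            _draw_panel(ax, pentad.panels[key],
                        f"{key} (n={pentad.counts[key]})", norm, cmap)
    elif pentad.mode == "distance":
        strata = pentad.strata or []
        n_strata = max(len(strata) - 1, 1)
        fig, axes = plt.subplots(3, n_strata + 1, figsize=(2.2 * (n_strata + 1), 6),
                                 squeeze=False)
        for ax in axes.ravel():
            ax.set_visible(False)
        for r, key in enumerate(["A_short", "B_short"]):
            ax = axes[r, 0]
            ax.set_visible(True)
            _draw_panel(ax, pentad.panels[key],
                        f"{key} (n={pentad.counts[key]})", norm, cmap)
        for k in range(n_strata):
            label = f"{strata[k] / 1e6:g}-{strata[k + 1] / 1e6:g} Mb"
            for r, kind in enumerate(["A_long", "AB", "B_long"]):
                key = panel_key(kind, k)
                ax = axes[r, k + 1]
                ax.set_visible(True)
                _draw_panel(ax, pentad.panels[key],
                            f"{kind} {label} (n={pentad.counts[key]})", norm, cmap)
    else:  # pragma: no cover - modes are validated upstream
        raise PentadError(f"cannot render mode {pentad.mode!r}")
    fig.suptitle(f"average compartment ({pentad.mode})", fontsize=10)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# shared pipeline helpers

def _load_oe_and_intervals(cool_path, bedgraph_path, resolution, balanced,
                           exclude, mode):
    bins = read_genome_bins(cool_path, resolution=resolution)
    tracks = read_compartment_signal(bedgraph_path, bins)
    report = validate_inputs(bins, tracks)
    chroms = [c for c in report.shared_chromosomes if c not in exclude]
    if not chroms:
        raise PentadError("all shared chromosomes were excluded")
    intervals = {c: segment_signal(tracks[c]) for c in chroms}
    oe_maps = {}
    if mode in ("cis", "distance"):
        for c in chroms:
            obs = read_contact_matrix(cool_path, c, use_balanced=balanced,
                                      resolution=resolution)
            oe_maps[c] = oe_cis(obs, expected_cis(obs))
    else:
        for i, c1 in enumerate(chroms):
            for c2 in chroms[i + 1:]:
                obs = read_contact_matrix(cool_path, (c1, c2), use_balanced=balanced,
                                          resolution=resolution)
                oe_maps[(c1, c2)] = oe_trans(obs)
    return oe_maps, intervals


def _settings_from_options(rescale_size, min_dimension, max_zeros, cutoff,
                           distance_bins):
    bins = DEFAULT_DISTANCE_BINS
    if distance_bins:
        bins = tuple(float(b) for b in distance_bins.split(","))
    return PentadSettings(
        rescale_size=rescale_size, min_dimension=min_dimension,
        max_zero_fraction=max_zeros, max_distance=cutoff, distance_bins=bins,
    )


def _run_config(**kwargs) -> dict:
    return {"tool_version": __version__, **kwargs}


_common_options = [
    click.option("--resolution", type=int, default=None,
                 help="Bin size to read from a multi-resolution container."),
    click.option("--rescale-size", type=int, default=33, show_default=True,
                 help="Side length (odd) of the rescaled area squares."),
    click.option("--min-dimension", type=int, default=3, show_default=True,
                 help="Minimum area dimension in bins (filter 1)."),
    click.option("--max-zeros", type=float, default=0.5, show_default=True,
                 help="Maximum fraction of empty pixels per area (filter 2)."),
    click.option("--cutoff", type=float, default=None,
                 help="Maximum anchor distance in bp (filter 3); unset = no cutoff."),
    click.option("--exclude-chroms", default="", help="Comma-separated chromosomes to skip."),
    click.option("--no-balance", is_flag=True, help="Force raw counts even if weights exist."),
    click.option("--out-prefix", default="pentad", show_default=True),
    click.option("--figure/--no-figure", default=False, help="Also render a figure."),
    click.option("--format", "fig_format", type=click.Choice(["png", "svg", "pdf"]),
                 default="png", show_default=True),
]


def _with_options(options):
    def wrap(func):
        for option in reversed(options):
            func = option(func)
        return func
    return wrap


class _Group(click.Group):
    """Convert domain errors into one-line diagnostics (no stack traces)."""

    def invoke(self, ctx):
        try:
            return super().invoke(ctx)
        except PentadError as exc:
            raise click.ClickException(str(exc)) from exc


@click.group(cls=_Group)
@click.version_option(__version__)
@click.option("-v", "--verbose", is_flag=True, help="Enable debug logging.")
def main(verbose):
    """Average-compartment (pentad) analysis of Hi-C contact maps."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


def _pileup_command(mode):
    @click.argument("cool_path", type=click.Path())
    @click.argument("bedgraph_path", type=click.Path())
    @_with_options(_common_options)
    @click.option("--distance-bins", default="",
                  help="Comma-separated stratum boundaries in bp (distance mode).")
    def command(cool_path, bedgraph_path, resolution, rescale_size, min_dimension,
                max_zeros, cutoff, exclude_chroms, no_balance, out_prefix,
                figure, fig_format, distance_bins):
        settings = _settings_from_options(rescale_size, min_dimension, max_zeros,
                                          cutoff, distance_bins)
        exclude = {c for c in exclude_chroms.split(",") if c}
        balanced = False if no_balance else None
        oe_maps, intervals = _load_oe_and_intervals(
            cool_path, bedgraph_path, resolution, balanced, exclude, mode,
        )
        config = _run_config(
            mode=mode, cool_path=str(cool_path), bedgraph_path=str(bedgraph_path),
            resolution=resolution, exclude_chroms=sorted(exclude),
            no_balance=no_balance, settings=settings.to_dict(),
        )
        pentad = build_pentad(oe_maps, intervals, mode=mode, settings=settings,
                              provenance={"run_config": config})
        out_json = f"{out_prefix}.json"
        pentad.save(out_json)
        click.echo(f"wrote {out_json}")
        if figure:
            out_fig = f"{out_prefix}.{fig_format}"
            render_pentad(pentad, path=out_fig)
            click.echo(f"wrote {out_fig}")
    command.__name__ = mode
    return command


for _mode, _help in [
    ("cis", "Average compartment from within-chromosome interactions."),
    ("trans", "Average compartment from between-chromosome interactions."),
    ("distance", "Average compartment stratified by anchor distance."),
]:
    main.command(name=_mode, help=_help)(_pileup_command(_mode))


@main.command(help="Per-chromosome compartment strength table.")
@click.argument("cool_path", type=click.Path())
@click.argument("bedgraph_path", type=click.Path())
@_with_options(_common_options[:7])  # resolution .. no-balance
@click.option("--crop", type=float, default=0.25, show_default=True,
              help="Fraction of the AB panel cropped from each side.")
@click.option("--out-prefix", default="pentad", show_default=True)
def strength(cool_path, bedgraph_path, resolution, rescale_size, min_dimension,
             max_zeros, cutoff, exclude_chroms, no_balance, crop, out_prefix):
    settings = _settings_from_options(rescale_size, min_dimension, max_zeros,
                                      cutoff, "")
    exclude = {c for c in exclude_chroms.split(",") if c}
    balanced = False if no_balance else None
    oe_maps, intervals = _load_oe_and_intervals(
        cool_path, bedgraph_path, resolution, balanced, exclude, "cis",
    )
    table = strength_genome(oe_maps, intervals, settings=settings, crop_fraction=crop)
    out_tsv = f"{out_prefix}_strength.tsv"
    config = _run_config(mode="strength", cool_path=str(cool_path),
                         bedgraph_path=str(bedgraph_path), crop=crop,
                         settings=settings.to_dict())
    write_strength_table(table, out_tsv, provenance={"run_config": config})
    click.echo(f"wrote {out_tsv}")


@main.command(help="Wilcoxon signed-rank comparison of two strength tables.")
@click.argument("table_1", type=click.Path())
@click.argument("table_2", type=click.Path())
@click.option("--out-prefix", default="pentad", show_default=True)
def compare(table_1, table_2, out_prefix):
    t1 = read_strength_table(table_1)
    t2 = read_strength_table(table_2)
    report = compare_conditions(t1, t2)
    out_tsv = f"{out_prefix}_comparison.tsv"
    config = _run_config(mode="compare", table_1=str(table_1), table_2=str(table_2))
    write_comparison(report, out_tsv, provenance={"run_config": config})
    click.echo(f"wrote {out_tsv}")


@main.command(help="Render a stored pile-up JSON as a figure.")
@click.argument("pentad_json", type=click.Path())
@click.option("--out-prefix", default="pentad", show_default=True)
@click.option("--format", "fig_format", type=click.Choice(["png", "svg", "pdf"]),
              default="png", show_default=True)
@click.option("--vmin", type=float, default=0.5, show_default=True)
@click.option("--vmax", type=float, default=2.0, show_default=True)
def plot(pentad_json, out_prefix, fig_format, vmin, vmax):
    pentad = Pentad.load(pentad_json)
    out_fig = f"{out_prefix}.{fig_format}"
    render_pentad(pentad, path=out_fig, vmin=vmin, vmax=vmax)
    click.echo(f"wrote {out_fig}")


@main.command(help="Write a synthetic cooler + bedGraph fixture.")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--n-chroms", type=int, default=2, show_default=True)
@click.option("--chrom-length", type=int, default=50_000_000, show_default=True)
@click.option("--binsize", type=int, default=100_000, show_default=True)
@click.option("--contrast", "f", type=float, default=2.0, show_default=True,
              help="Planted within/between O/E contrast f (f=1 is a null).")
@click.option("--alpha", type=float, default=1.0, show_default=True)
@click.option("--depth", type=float, default=1000.0, show_default=True)
@click.option("--noise", type=click.Choice(["none", "poisson"]), default="none",
              show_default=True)
@click.option("--missing-fraction", type=float, default=0.0, show_default=True)
@click.option("--trans", is_flag=True, help="Also generate trans matrices.")
@click.option("--out-prefix", default="synthetic", show_default=True)
def simulate(seed, n_chroms, chrom_length, binsize, f, alpha, depth, noise,
             missing_fraction, trans, out_prefix):
    spec = SyntheticSpec(
        chromsizes={f"chr{i + 1}": chrom_length for i in range(n_chroms)},
        binsize=binsize, f=f, alpha=alpha, depth=depth, noise=noise,
        missing_fraction=missing_fraction, trans=trans, seed=seed,
    )
    genome = generate_genome(spec)
    paths = write_fixture(genome, out_prefix)
    for kind, path in paths.items():
        click.echo(f"wrote {path}")


if __name__ == "__main__":  # pragma: no cover
    main()
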