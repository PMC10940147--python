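"""Access to the human mtDNA reference (rCRS, NC_012920.1, 16,569 bp).

The sequence itself is not bundled. ``load_rcrs`` looks for a local copy
(a ``data/NC_012920.1.fasta`` next to the repository root, an explicit
path, or the user cache) and ``fetch_rcrs`` performs a one-time ~17 kb
download from NCBI efetch when a network is available, caching the FASTA
for later runs.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

from .genome import CircularGenome, load_genome

ACCESSION = "NC_012920.1"
RCRS_LENGTH = 16569
EFETCH_URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    f"?db=nuccore&id={ACCESSION}&rettype=fasta&retmode=text"
)


def default_cache_path() -> Path:
    return Path.home() / ".cache" / "mitobe" / f"{ACCESSION}.fasta"


def candidate_paths() -> list[Path]:
    here = Path(__file__).resolve()
    repo_data = here.parents[2] / "data" / f"{ACCESSION}.fasta"
    return [repo_data, Path(f"data/{ACCESSION}.fasta"), default_cache_path()]


def fetch_rcrs(dest: str | Path | None = None, timeout: float = 30.0) -> Path:
    """Download the rCRS FASTA from NCBI (one-time, ~17 kb) into ``dest``
    (default: the user cache). Raises on network failure."""
    dest = Path(dest) if dest else default_cache_path()
    dest.parent.mkdir(parents=True, exist_ok=True)
    with urllib.request.urlopen(EFETCH_URL, timeout=timeout) as resp:
        text = resp.read().decode()
    if not text.startswith(">"):
        raise RuntimeError("unexpected response from NCBI efetch")
    dest.write_text(text)
    return dest


def load_rcrs(path: str | Path | None = None, allow_fetch: bool = False,
              timeout: float = 10.0) -> CircularGenome:
    """Load the rCRS from a local copy, optionally fetching it first.

    Raises FileNotFoundError with guidance when no copy exists and
    fetching is disabled or fails.
    """
    paths = [Path(path)] if path else candidate_paths()
    for p in paths:
        if p.exists():
            g = load_genome(p)
            _check(g)
            return g
    if allow_fetch:
        try:
            fetched = fetch_rcrs(timeout=timeout)
        except Exception as e:  # noqa: BLE001 - network errors vary widely
            raise FileNotFoundError(
                f"rCRS ({ACCESSION}) not found locally and fetch failed ({e}); "
                f"place the FASTA at one of {[str(p) for p in candidate_paths()]}"
            ) from e
        g = load_genome(fetched)
        _check(g)
        return g
    raise FileNotFoundError(
        f"rCRS ({ACCESSION}) not found; run fetch_rcrs() once (needs network) or "
        f"place the FASTA at one of {[str(p) for p in candidate_paths()]}")


def _check(g: CircularGenome) -> None:
    if g.length != RCRS_LENGTH:
        raise ValueError(
            f"loaded sequence has length {g.length}, expected {RCRS_LENGTH} "
            f"for {ACCESSION}; is this really the rCRS?")
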