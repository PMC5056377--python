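"""Minimal JCAMP-DX reader/writer for single-block infrared spectra.

Supports ``##XYDATA=(X++(Y..Y))`` tables in AFFN or ASDF squeezed form
(SQZ digits, DIF differences, DUP repeats) plus plain ``##XYPOINTS=(XY..XY)``
pairs.  Compound (multi-block / ##BLOCKS) files are rejected with a clear
message — this module deliberately covers only the subset needed to exchange
absorbance spectra, not the whole JCAMP-DX standard.

Writing always emits AFFN: ``(X++(Y..Y))`` for evenly spaced grids,
``(XY..XY)`` otherwise, with enough digits for 1e-9 round-trip fidelity.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .errors import SpectrumFormatError

# ASDF pseudo-digit alphabets
_SQZ = {"@": 0, **{chr(ord("A") + i): i + 1 for i in range(9)},
        **{chr(ord("a") + i): -(i + 1) for i in range(9)}}
_DIF = {"%": 0, **{chr(ord("J") + i): i + 1 for i in range(9)},
        **{chr(ord("j") + i): -(i + 1) for i in range(9)}}
_DUP = {**{chr(ord("S") + i): i + 1 for i in range(8)}, "s": 9}

_TOKEN_RE = re.compile(
    r"[+-]?\d+(?:\.\d*)?(?:[eE][+-]?\d+)?"   # AFFN number
    r"|[@%A-Za-z][0-9]*(?:\.[0-9]*)?"        # ASDF pseudo-digit token
)


def _decode_pseudo(tok: str) -> tuple[str, float]:
    """Return (mode, value) for an ASDF token; mode in {sqz, dif, dup}."""
    c, rest = tok[0], tok[1:]
    for mode, table in (("sqz", _SQZ), ("dif", _DIF), ("dup", _DUP)):
        if c in table:
            digit = table[c]
            if mode == "dup":
                return mode, float(str(digit) + rest)
            sign = -1.0 if digit < 0 else 1.0
            return mode, sign * float(str(abs(digit)) + (rest or ""))
    raise SpectrumFormatError(f"unrecognized ASDF token {tok!r}")


def _decode_table_line(line: str, last_y: float | None,
                       prev_dif: bool) -> tuple[float, list[float], bool]:
    """Decode one XYDATA line -> (x, y values, line_ended_in_dif)."""
    tokens = _TOKEN_RE.findall(line)
    if not tokens:
        raise SpectrumFormatError(f"empty data line {line!r}")
    try:
        x = float(tokens[0])
    except ValueError:
        raise SpectrumFormatError(
            f"data line must start with an AFFN abscissa: {line!r}") from None
    ys: list[float] = []
    mode = "val"
    last_dif = 0.0
    for tok in tokens[1:]:
        try:
            ys.append(float(tok))
            mode = "val"
            continue
        except ValueError:
            pass
        kind, value = _decode_pseudo(tok)
        if kind == "sqz":
            ys.append(value)
            mode = "val"
        elif kind == "dif":
            base = ys[-1] if ys else (last_y if last_y is not None else 0.0)
            ys.append(base + value)
            last_dif = value
            mode = "dif"
        else:  # dup: repeat previous operation value-1 more times
            n = int(value) - 1
            if n < 0 or (not ys and last_y is None):
                raise SpectrumFormatError(f"DUP token {tok!r} with nothing to repeat")
            for _ in range(n):
                if mode == "dif":
                    ys.append(ys[-1] + last_dif)
                else:
                    ys.append(ys[-1])
    if prev_dif and ys:
        # first ordinate of a line following a DIF line is a check value
        if last_y is not None and abs(ys[0] - last_y) > 1e-6 * max(1.0, abs(last_y)):
            raise SpectrumFormatError(
                f"DIF check value mismatch: expected {last_y}, got {ys[0]}")
        ys = ys[1:]
    return x, ys, mode == "dif"


def read(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a single-block JCAMP-DX file -> (wavenumbers, absorbance, meta)."""
    path = Path(path)
    text = path.read_text(errors="replace")
    if re.search(r"^##BLOCKS\s*=", text, flags=re.MULTILINE):
        raise SpectrumFormatError(
            f"{path}: compound (multi-block) JCAMP-DX files are not supported; "
            "split the file into single blocks")
    if len(re.findall(r"^##TITLE\s*=", text, flags=re.MULTILINE)) > 1:
        raise SpectrumFormatError(
            f"{path}: multiple ##TITLE blocks found; only single-block files "
            "are supported")

    records: dict[str, str] = {}
    meta: dict[str, str] = {}
    table_lines: list[str] = []
    table_kind: str | None = None
    current_label: str | None = None
    for raw in text.splitlines():
        line = raw.split("$$", 1)[0].rstrip()      # strip inline comments
        if not line.strip():
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.strip().upper().replace(" ", "")
            value = value.strip()
            current_label = label
            if label in ("XYDATA", "XYPOINTS"):
                table_kind = label
                if "XY..XY" in value.upper().replace(" ", ""):
                    table_kind = "XYPOINTS"
            elif label == "END":
                current_label = None
            elif label.startswith("$"):
                meta[label[1:].lower()] = value
            else:
                records[label] = value
        elif current_label in ("XYDATA", "XYPOINTS"):
            table_lines.append(line)
    if table_kind is None or not table_lines:
        raise SpectrumFormatError(f"{path}: no ##XYDATA/##XYPOINTS table found")

    xfactor = float(records.get("XFACTOR", "1") or 1)
    yfactor = float(records.get("YFACTOR", "1") or 1)

    if table_kind == "XYPOINTS":
        xs, ys = [], []
        for line in table_lines:
            nums = [float(t) for t in _TOKEN_RE.findall(line)]
            if len(nums) % 2:
                raise SpectrumFormatError(
                    f"{path}: odd number of values in XYPOINTS line {line!r}")
            xs.extend(nums[0::2])
            ys.extend(nums[1::2])
        wn = np.asarray(xs) * xfactor
        ab = np.asarray(ys) * yfactor
    else:
        ys_all: list[float] = []
        last_y: float | None = None
        prev_dif = False
        for line in table_lines:
            _, ys, prev_dif = _decode_table_line(line, last_y, prev_dif)
            ys_all.extend(ys)
            if ys_all:
                last_y = ys_all[-1]
        npoints = int(float(records.get("NPOINTS", str(len(ys_all)))))
        if npoints != len(ys_all):
            raise SpectrumFormatError(
                f"{path}: NPOINTS={npoints} but table has {len(ys_all)} ordinates")
        try:
            firstx = float(records["FIRSTX"])
            lastx = float(records["LASTX"])
        except KeyError as exc:
            raise SpectrumFormatError(f"{path}: missing required record {exc}")
        wn = np.linspace(firstx, lastx, npoints)
        ab = np.asarray(ys_all) * yfactor

    if "TITLE" in records:
        meta.setdefault("title", records["TITLE"])
    return wn, ab, meta


def write(wavenumbers: np.ndarray, absorbance: np.ndarray, meta: dict,
          path: str | Path) -> None:
    """Write an AFFN single-block JCAMP-DX file."""
    wn = np.asarray(wavenumbers, float)
    ab = np.asarray(absorbance, float)
    path = Path(path)
    steps = np.diff(wn)
    even = np.allclose(steps, steps[0], rtol=0, atol=1e-9 * max(1.0, abs(steps[0])))
    lines = [
        f"##TITLE={meta.get('title', 'cystir spectrum')}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        "##XFACTOR=1",
        "##YFACTOR=1",
        f"##FIRSTX={wn[0]:.12g}",
        f"##LASTX={wn[-1]:.12g}",
        f"##NPOINTS={wn.size}",
        f"##FIRSTY={ab[0]:.12g}",
    ]
    for key in sorted(meta):
        if key == "title":
            continue
        lines.append(f"##${key}={meta[key]}")
    if even:
        lines.append(f"##DELTAX={steps[0]:.12g}")
        lines.append("##XYDATA=(X++(Y..Y))")
        per_line = 4
        for i in range(0, wn.size, per_line):
            ys = " ".join(f"{y:.12g}" for y in ab[i:i + per_line])
            lines.append(f"{wn[i]:.12g} {ys}")
    else:
        lines.append("##XYPOINTS=(XY..XY)")
        for x, y in zip(wn, ab):
            lines.append(f"{x:.12g}, {y:.12g}")
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")
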