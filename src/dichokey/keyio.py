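"""Serialization: canonical text, XML round-trip, hyperlinked HTML, minimal
RTF, figure-image resolution, and the self-contained interactive browser.

The canonical text dialect is the bracketed layout that :mod:`.parser`
re-reads exactly: first lead ``N. <text>\t<ref>``, further leads
``– <text>\t<ref>``, pointers printed as bare integers and endpoints as their
labels.  The XML dialect is this project's own, versioned schema (root
``<dkey version="1">``) intended as a stable exchange format.

Exports other than XML refuse structurally broken keys: renumbering should be
done before a key is exported.
"""

from __future__ import annotations

import base64
import json
import mimetypes
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from html import escape
from pathlib import Path
from string import Template

from ._browser import BROWSER_TEMPLATE
from .model import Couplet, Endpoint, Key, Lead, Pointer, unique_endpoints
from .traversal import partition_endpoints
from .validator import is_valid, validate

__all__ = [
    "ExportError",
    "XmlSchemaError",
    "ImageBinding",
    "to_text",
    "to_xml",
    "from_xml",
    "to_html",
    "to_rtf",
    "resolve_images",
    "build_browser",
]

XML_VERSION = "1"
IMAGE_EXTENSIONS = ("png", "jpg", "jpeg", "gif", "svg")
DEFAULT_IMAGE_STEMS = ("fig{n}", "figure{n}")


class ExportError(ValueError):
    """An export was refused because the key is structurally broken."""


class XmlSchemaError(ValueError):
    """An XML document does not match the key schema."""


@dataclass(frozen=True)
class ImageBinding:
    """A figure image resolved for one lead.

    ``couplet``/``lead_index`` locate the lead, ``figure`` is the cited
    figure number, and ``path`` is the image file bound to it.
    """

    couplet: int
    lead_index: int
    figure: int
    path: Path


def _require_valid(key: Key, what: str) -> None:
    errors = [i for i in validate(key) if i.severity == "error"]
    if errors:
        codes = ", ".join(sorted({i.code for i in errors}))
        raise ExportError(f"{what} export refused: key has errors ({codes})")


def _format_reference(ref: Pointer | Endpoint) -> str:
    return str(ref.target) if isinstance(ref, Pointer) else ref.label


def to_text(key: Key) -> str:
    """Serialize a key to the canonical bracketed text dialect.

    One lead per line, tab before the reference, couplets in row order, no
    blank lines, LF line endings.  Refused while couplet numbers are
    duplicated — renumber first.
    """
    numbers = key.numbers()
    if len(set(numbers)) != len(numbers):
        raise ExportError("text export refused: duplicate couplet numbers; renumber first")
    lines = []
    for couplet in key.couplets:
        for i, lead in enumerate(couplet.leads):
            prefix = f"{couplet.number}." if i == 0 else "–"
            lines.append(f"{prefix} {lead.text}\t{_format_reference(lead.reference)}")
    return "\n".join(lines) + ("\n" if lines else "")


def to_xml(key: Key) -> str:
    """Serialize a key to the project's versioned XML exchange dialect.

    Any key state is serializable, including transiently broken ones; XML is
    the save format, not a publication export.
    """
    root = ET.Element("dkey", version=XML_VERSION)
    if key.title:
        ET.SubElement(root, "title").text = key.title
    for couplet in key.couplets:
        c_el = ET.SubElement(root, "couplet", number=str(couplet.number))
        for lead in couplet.leads:
            l_el = ET.SubElement(c_el, "lead")
            ET.SubElement(l_el, "text").text = lead.text
            if isinstance(lead.reference, Pointer):
                ET.SubElement(l_el, "pointer").text = str(lead.reference.target)
            else:
                ET.SubElement(l_el, "endpoint").text = lead.reference.label
    ET.indent(root)
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(
        root, encoding="unicode"
    ) + "\n"


def _schema_error(element: str, detail: str, index: int | None = None) -> XmlSchemaError:
    where = f"<{element}>" + (f" #{index}" if index is not None else "")
    return XmlSchemaError(f"{where}: {detail}")


def from_xml(document: str) -> Key:
    """Parse the XML exchange dialect back into a Key.

    Raises :class:`XmlSchemaError` naming the offending element (XML syntax
    errors carry line/column from the underlying parser).
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise XmlSchemaError(f"not well-formed XML: {exc}") from exc
    if root.tag != "dkey":
        raise _schema_error(root.tag, "root element must be <dkey>")
    key = Key()
    for index, child in enumerate(root, start=1):
        if child.tag == "title":
            key.title = child.text or ""
            continue
        if child.tag != "couplet":
            raise _schema_error(child.tag, "expected <couplet> or <title>", index)
        number_text = child.get("number")
        if number_text is None or not number_text.isdigit() or int(number_text) < 1:
            raise _schema_error(
                "couplet", f"number attribute must be a positive integer, got {number_text!r}",
                index,
            )
        leads: list[Lead] = []
        for l_index, l_el in enumerate(child, start=1):
            if l_el.tag != "lead":
                raise _schema_error(l_el.tag, "expected <lead>", l_index)
            text_el = l_el.find("text")
            if text_el is None:
                raise _schema_error("lead", "missing <text> child", l_index)
            pointer_el = l_el.find("pointer")
            endpoint_el = l_el.find("endpoint")
            if (pointer_el is None) == (endpoint_el is None):
                raise _schema_error(
                    "lead", "needs exactly one of <pointer> or <endpoint>", l_index
                )
            if pointer_el is not None:
                target = (pointer_el.text or "").strip()
                if not target.isdigit() or int(target) < 1:
                    raise _schema_error(
                        "pointer", f"content must be a positive integer, got {target!r}",
                        l_index,
                    )
                reference: Pointer | Endpoint = Pointer(int(target))
            else:
                label = (endpoint_el.text or "").strip()
                if not label:
                    raise _schema_error("endpoint", "label must be non-empty", l_index)
                reference = Endpoint(label)
            leads.append(Lead(text_el.text or "", reference))
        if not leads:
            raise _schema_error("couplet", "holds no <lead> children", index)
        key.couplets.append(Couplet(int(number_text), leads))
    return key


_HTML_PAGE = Template("""<!DOCTYPE html>
<html lang="en">
<head><meta charset="utf-8"><title>$title</title></head>
<body>
<h1>$title</h1>
$couplets
</body>
</html>
""")


def to_html(key: Key, image_dir: str | Path | None = None) -> str:
    """Render a valid key as one hyperlinked HTML page.

    Each couplet gets an anchor ``couplet-N``; pointers render as in-page
    links, endpoints are emphasized, resolved figure images render inline
    beside their lead, and all key text is HTML-escaped.
    """
    _require_valid(key, "HTML")
    blocks = []
    for couplet in key.couplets:
        rows = []
        for i, lead in enumerate(couplet.leads):
            marker = f"{couplet.number}." if i == 0 else "–"
            if isinstance(lead.reference, Pointer):
                ref_html = (
                    f'<a href="#couplet-{lead.reference.target}">'
                    f"{lead.reference.target}</a>"
                )
            else:
                ref_html = f"<em>{escape(lead.reference.label)}</em>"
            images = ""
            if image_dir is not None:
                images = "".join(
                    f'<br><img src="{escape(str(p))}" alt="figure">'
                    for p in resolve_images(lead.text, image_dir)
                )
            rows.append(
                f"<p>{escape(marker)} {escape(lead.text)} … {ref_html}{images}</p>"
            )
        blocks.append(
            f'<div id="couplet-{couplet.number}">\n' + "\n".join(rows) + "\n</div>"
        )
    return _HTML_PAGE.substitute(
        title=escape(key.title or "Identification key"), couplets="\n".join(blocks)
    )


def _rtf_escape(text: str) -> str:
    out = []
    for ch in text:
        if ch in "\\{}":
            out.append("\\" + ch)
        elif ord(ch) > 127:
            code = ord(ch)
            if code > 32767:  # RTF \u takes a signed 16-bit value
                code -= 65536
            out.append(f"\\u{code}?")
        else:
            out.append(ch)
    return "".join(out)


def to_rtf(key: Key) -> str:
    """Render a valid key as a minimal rich-text (RTF) document.

    One paragraph per lead, couplet numbers emphasized in bold, non-ASCII
    characters written as signed Unicode escapes; the content text is
    identical to :func:`to_text` modulo markup.  The styling is deliberately
    plain so journals and word processors can restyle it.
    """
    _require_valid(key, "RTF")
    lines = [
        "{\\rtf1\\ansi\\ansicpg65001\\deff0",
        "{\\fonttbl{\\f0 Times New Roman;}}",
        "\\f0\\fs22",
    ]
    for couplet in key.couplets:
        for i, lead in enumerate(couplet.leads):
            prefix = (
                f"{{\\b {couplet.number}.}}" if i == 0 else "\\u8211?"
            )  # – en dash
            lines.append(
                f"{prefix} {_rtf_escape(lead.text)}\\tab "
                f"{_rtf_escape(_format_reference(lead.reference))}\\par"
            )
    lines.append("}")
    return "\n".join(lines) + "\n"


# "Fig. 12", "Figs 3, 4", "Fig. 5–7" — the keyword followed by one or more
# comma/dash-separated integers.
_FIG_RE = re.compile(r"\bFigs?\.?\s*(\d+(?:\s*[,–—-]\s*\d+)*)")
_INT_RE = re.compile(r"\d+")


def figure_numbers(lead_text: str) -> list[int]:
    """Figure numbers cited in a lead text, in order of appearance."""
    numbers: list[int] = []
    for match in _FIG_RE.finditer(lead_text):
        numbers.extend(int(m) for m in _INT_RE.findall(match.group(1)))
    return numbers


def resolve_images(
    lead_text: str,
    image_dir: str | Path | None,
    stems: tuple[str, ...] = DEFAULT_IMAGE_STEMS,
) -> list[Path]:
    """Find the image files for the figures a lead text cites.

    For each cited figure number ``n``, the first existing file whose stem
    matches ``fig<n>`` or ``figure<n>`` case-insensitively, with extension
    png/jpg/jpeg/gif/svg, is bound; unmatched numbers are skipped silently.
    An absent or unreadable directory yields an empty result.  The stem
    patterns are configurable (``{n}`` is the figure number).
    """
    if image_dir is None:
        return []
    directory = Path(image_dir)
    if not directory.is_dir():
        return []
    listing = {
        p.name.lower(): p
        for p in sorted(directory.iterdir(), reverse=True)
        if p.is_file()
    }  # reverse+dict: the alphabetically first of case-colliding names wins
    found: list[Path] = []
    for n in figure_numbers(lead_text):
        for stem in stems:
            name = stem.format(n=n)
            hit = next(
                (
                    listing[f"{name}.{ext}"]
                    for ext in IMAGE_EXTENSIONS
                    if f"{name}.{ext}" in listing
                ),
                None,
            )
            if hit is not None:
                if hit not in found:
                    found.append(hit)
                break
    return found


def _data_uri(path: Path) -> str:
    mime = mimetypes.guess_type(path.name)[0] or "application/octet-stream"
    payload = base64.b64encode(path.read_bytes()).decode("ascii")
    return f"data:{mime};base64,{payload}"


def browser_data(key: Key, image_dir: str | Path | None = None) -> dict:
    """The structured payload embedded in the generated browser page.

    Couplet leads with their references and inlined images, the precomputed
    remaining/excluded partition for every couplet, and the full taxon list.
    """
    couplets = {}
    for couplet in key.couplets:
        leads = []
        for lead in couplet.leads:
            ref = lead.reference
            leads.append(
                {
                    "text": lead.text,
                    "pointer": ref.target if isinstance(ref, Pointer) else None,
                    "endpoint": ref.label if isinstance(ref, Endpoint) else None,
                    "images": [
                        _data_uri(p) for p in resolve_images(lead.text, image_dir)
                    ],
                }
            )
        couplets[str(couplet.number)] = {"leads": leads}
    partitions = {
        str(c.number): {
            "remaining": list(partition_endpoints(key, c.number).remaining),
            "excluded": list(partition_endpoints(key, c.number).excluded),
        }
        for c in key.couplets
    }
    return {
        "title": key.title or "Identification key",
        "start": 1,
        "couplets": couplets,
        "partitions": partitions,
        "taxa": unique_endpoints(key),
    }


def build_browser(
    key: Key,
    image_dir: str | Path | None = None,
    output_path: str | Path | None = None,
) -> str:
    """Generate the single-file interactive key browser.

    The page shows five panels — the two leads of the current couplet (with
    figures), the path, and the remaining and excluded endpoints.  Clicking a
    pointer lead advances, clicking a path entry backtracks, and choosing an
    endpoint lead shows the identified taxon.  Everything, images included,
    is embedded, so the file works offline and can be mailed around.

    Returns the HTML text; writes it to ``output_path`` when given.
    """
    _require_valid(key, "browser")
    data = browser_data(key, image_dir)
    key_json = json.dumps(data, ensure_ascii=False, indent=1).replace("</", "<\\/")
    html = BROWSER_TEMPLATE.substitute(
        title=escape(data["title"]), key_json=key_json
    )
    if output_path is not None:
        Path(output_path).write_text(html, encoding="utf-8")
    return html
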