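"""Export a key for publication and build the interactive browser page.

Text output is ready for a journal manuscript; XML is the save/exchange
format; RTF opens in word processors; and the browser is a single portable
HTML file with the classic five panels (two leads, path, remaining and
excluded endpoints) and all images inlined.
"""

from pathlib import Path

from dichokey import FixtureSpec, build_browser, generate_key, to_rtf, to_text, to_xml

key = generate_key(FixtureSpec(couplets=5, seed=3))
out = Path("scratch_example_out")
out.mkdir(exist_ok=True)

(out / "key.txt").write_text(to_text(key), encoding="utf-8")
(out / "key.xml").write_text(to_xml(key), encoding="utf-8")
(out / "key.rtf").write_text(to_rtf(key), encoding="utf-8")
html = build_browser(key, output_path=out / "key.html")

print(to_text(key))
print(f"text/xml/rtf/browser written to {out}/")
print(f"browser page: {len(html)} characters, self-contained "
      f"(open key.html in any web browser)")
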