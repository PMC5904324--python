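"""Static template for the single-file interactive key browser.

The browser mirrors the classic five-window layout: the two leads of the
current couplet on top (with any linked figures), and below them the path
(identification history), the remaining endpoints and the excluded endpoints.
All key data and per-couplet endpoint partitions are embedded as JSON, and
images are inlined as data URIs, so the generated file is fully portable and
references no external resource.
"""

from string import Template

BROWSER_TEMPLATE = Template(r"""<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>$title</title>
<style>
  body { font-family: Georgia, serif; margin: 0; background: #f4f1ea; color: #222; }
  header { background: #3d5a40; color: #fff; padding: 0.6em 1em; }
  header h1 { font-size: 1.1em; margin: 0; font-weight: normal; }
  #browser { display: grid; grid-template-rows: auto auto; gap: 8px; padding: 8px; }
  #leads { display: grid; grid-template-columns: 1fr 1fr; gap: 8px; }
  #lists { display: grid; grid-template-columns: 1fr 1fr 1fr; gap: 8px; }
  .panel { background: #fff; border: 1px solid #c8c2b4; border-radius: 4px;
           padding: 0.6em; min-height: 7em; }
  .panel h2 { font-size: 0.8em; text-transform: uppercase; letter-spacing: 0.05em;
              color: #666; margin: 0 0 0.5em 0; }
  .lead { cursor: pointer; }
  .lead:hover { background: #f0ead8; }
  .lead .ref { font-weight: bold; color: #3d5a40; }
  .lead img { max-width: 100%; display: block; margin-top: 0.5em; }
  #path li { cursor: pointer; color: #345; }
  #path li:hover { text-decoration: underline; }
  ul { margin: 0; padding-left: 1.4em; }
  #result { font-style: italic; font-size: 1.2em; color: #3d5a40; }
  .muted { color: #999; }
  button { margin-top: 0.4em; }
</style>
</head>
<body>
<header><h1 id="heading">$title</h1></header>
<div id="browser">
  <div id="leads">
    <div class="panel" id="lead0"><h2>Lead 1</h2><div class="body"></div></div>
    <div class="panel" id="lead1"><h2>Lead 2</h2><div class="body"></div></div>
  </div>
  <div id="lists">
    <div class="panel"><h2>Path</h2><ul id="path"></ul>
      <button id="restart">Restart</button></div>
    <div class="panel"><h2>Remaining endpoints</h2><ul id="remaining"></ul></div>
    <div class="panel"><h2>Excluded endpoints</h2><ul id="excluded"></ul></div>
  </div>
</div>
<script id="key-data" type="application/json">
$key_json
</script>
<script>
"use strict";
const DATA = JSON.parse(document.getElementById("key-data").textContent);
let path = [];          // [{couplet, lead}]
let current = DATA.start;
let result = null;

function el(id) { return document.getElementById(id); }

function fill(listId, items, muted) {
  const ul = el(listId);
  ul.innerHTML = "";
  for (const item of items) {
    const li = document.createElement("li");
    li.textContent = item;
    if (muted) li.classList.add("muted");
    ul.appendChild(li);
  }
}

function leadSummary(couplet, index) {
  const lead = DATA.couplets[couplet].leads[index];
  const text = lead.text ? lead.text : "(no text)";
  return couplet + ". " + text;
}

function choose(index) {
  if (result !== null) return;
  const lead = DATA.couplets[current].leads[index];
  path.push({couplet: current, lead: index});
  if (lead.pointer !== null) {
    if (path.some(step => step.couplet === lead.pointer)) {
      path.pop();
      alert("Couplet " + lead.pointer + " is already on the path (cycle).");
      return;
    }
    current = lead.pointer;
  } else {
    result = lead.endpoint;
  }
  render();
}

function backtrack(position) {
  if (position < path.length) {
    current = path[position].couplet;
    path = path.slice(0, position);
  }
  result = null;
  render();
}

function renderLead(panel, couplet, index) {
  const body = panel.querySelector(".body");
  body.innerHTML = "";
  const leads = DATA.couplets[couplet].leads;
  if (index >= leads.length) { return; }
  const lead = leads[index];
  const div = document.createElement("div");
  div.className = "lead";
  const text = document.createElement("span");
  text.textContent = (lead.text ? lead.text : "(no text)") + " ";
  const ref = document.createElement("span");
  ref.className = "ref";
  ref.textContent = lead.pointer !== null ? "→ " + lead.pointer : lead.endpoint;
  div.appendChild(text);
  div.appendChild(ref);
  for (const uri of lead.images) {
    const img = document.createElement("img");
    img.src = uri;
    div.appendChild(img);
  }
  div.onclick = () => choose(index);
  body.appendChild(div);
}

function render() {
  if (result !== null) {
    el("lead0").querySelector(".body").innerHTML =
      '<div id="result"></div>';
    document.getElementById("result").textContent = "Identified as: " + result;
    el("lead1").querySelector(".body").innerHTML = "";
  } else {
    renderLead(el("lead0"), current, 0);
    renderLead(el("lead1"), current, 1);
  }
  const ul = el("path");
  ul.innerHTML = "";
  path.forEach((step, i) => {
    const li = document.createElement("li");
    li.textContent = leadSummary(step.couplet, step.lead);
    li.onclick = () => backtrack(i);
    ul.appendChild(li);
  });
  const part = result !== null
    ? {remaining: [result], excluded: DATA.taxa.filter(t => t !== result)}
    : DATA.partitions[current];
  fill("remaining", part.remaining, false);
  fill("excluded", part.excluded, true);
}

el("restart").onclick = () => backtrack(0);
render();
</script>
</body>
</html>
""")
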