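<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" width="442.00" height="80.00" font-family="Helvetica,Arial,sans-serif" font-size="8.00"><g id="chrom:chr1" class="panel"><text id="label:chr1" class="chrom-label" x="60.00" y="22.00">chr1</text><rect id="outline:chr1" class="rod-outline" x="60.00" y="26.00" width="22.00" height="40.00" fill="none" rx="11.00" stroke="#444444" stroke-width="0.8" fill-opacity="0" /><rect id="band:chr1:p12" class="band" x="60.00" y="26.00" width="22.00" height="19.91" fill="#ffffff" stroke="#555555" stroke-width="0.4" /><text id="bandlabel:chr1:p12" class="band-label" x="14.00" y="39.95">p12</text><polygon id="band:chr1:p11" class="band acen" points="60.00,45.91 82.00,45.91 71.00,46.71" fill="#cc4444" stroke="#555555" stroke-width="0.5" /><text id="bandlabel:chr1:p11" class="band-label" x="14.00" y="50.31">p11</text><polygon id="band:chr1:q11" class="band acen" points="60.00,46.71 82.00,46.71 71.00,47.51" fill="#cc4444" stroke="#555555" stroke-width="0.5" /><text id="bandlabel:chr1:q11" class="band-label" x="14.00" y="51.11">q11</text><rect id="band:chr1:q12" class="band" x="60.00" y="47.51" width="22.00" height="2.29" fill="#646464" stroke="#555555" stroke-width="0.4" /><text id="bandlabel:chr1:q12" class="band-label" x="14.00" y="52.65">q12</text><rect id="band:chr1:q13" class="band" x="60.00" y="49.79" width="22.00" height="16.21" fill="#000000" stroke="#555555" stroke-width="0.4" /><text id="bandlabel:chr1:q13" class="band-label" x="14.00" y="61.90">q13</text><line id="baseline:chr1" class="baseline" stroke="#888888" stroke-width="0.5" x1="150.00" x2="150.00" y1="26.00" y2="66.00" /><rect id="win:chr1:0" class="winbar gain" x="150.00" y="26.00" width="0.00" height="8.00" fill="#2c7d4f" /><rect id="win:chr1:1" class="winbar loss" x="120.00" y="34.00" width="30.00" height="8.00" fill="#c23b22" /><rect id="win:chr1:2" class="winbar loss" x="120.00" y="42.00" width="30.00" height="8.00" fill="#c23b22" /><rect id="win:chr1:3" class="winbar gain" x="150.00" y="50.00" width="9.00" height="8.00" fill="#2c7d4f" /><rect id="win:chr1:4" class="winbar undef" x="148.00" y="58.00" width="4.00" height="8.00" fill="#b0b0b0" /><line id="seg:chr1:0" class="segment loss" stroke="#c23b22" stroke-width="2.0" x1="213.00" x2="213.00" y1="34.00" y2="50.00" /><text id="seglabel:chr1:0" class="segment-label" x="216.00" y="42.00">q12</text></g><g id="chrom:chr2" class="panel"><text id="label:chr2" class="chrom-label" x="274.00" y="22.00">chr2</text><rect id="outline:chr2" class="rod-outline" x="274.00" y="26.00" width="22.00" height="24.00" fill="none" rx="11.00" stroke="#444444" stroke-width="0.8" fill-opacity="0" /><rect id="band:chr2:p13" class="band" x="274.00" y="26.00" width="22.00" height="2.15" fill="#c8c8c8" stroke="#555555" stroke-width="0.4" /><text id="bandlabel:chr2:p13" class="band-label" x="228.00" y="31.07">p13</text><rect id="band:chr2:p12" class="band" x="274.00" y="28.15" width="22.00" height="11.03" fill="#969696" stroke="#555555" stroke-width="0.4" /><text id="bandlabel:chr2:p12" class="band-label" x="228.00" y="37.66">p12</text><polygon id="band:chr2:p11" class="band acen" points="274.00,39.18 296.00,39.18 285.00,39.66" fill="#cc4444" stroke="#555555" stroke-width="0.5" /><text id="bandlabel:chr2:p11" class="band-label" x="228.00" y="43.42">p11</text><polygon id="band:chr2:q11" class="band acen" points="274.00,39.66 296.00,39.66 285.00,40.14" fill="#cc4444" stroke="#555555" stroke-width="0.5" /><text id="bandlabel:chr2:q11" class="band-label" x="228.00" y="43.90">q11</text><rect id="band:chr2:q12" class="band" x="274.00" y="40.14" width="22.00" height="2.22" fill="#ffffff" stroke="#555555" stroke-width="0.4" /><text id="bandlabel:chr2:q12" class="band-label" x="228.00" y="45.25">q12</text><rect id="band:chr2:q13" class="band" x="274.00" y="42.36" width="22.00" height="7.64" fill="#dcc8dc" stroke="#555555" stroke-width="0.4" /><text id="bandlabel:chr2:q13" class="band-label" x="228.00" y="50.18">q13</text><line id="baseline:chr2" class="baseline" stroke="#888888" stroke-width="0.5" x1="364.00" x2="364.00" y1="26.00" y2="50.00" /><rect id="win:chr2:0" class="winbar gain" x="364.00" y="26.00" width="0.00" height="8.00" fill="#2c7d4f" /><rect id="win:chr2:1" class="winbar gain" x="364.00" y="34.00" width="24.00" height="8.00" fill="#2c7d4f" /><rect id="win:chr2:2" class="winbar gain" x="364.00" y="42.00" width="0.00" height="8.00" fill="#2c7d4f" /></g></svg>
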