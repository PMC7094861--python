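"""VCF v4.2 output for consensus/annotated variants and the panel of normals.

INFO keys: DPA/DPB per-pool depth, ADA/ADB per-pool alt count, CVAF merged
allele fraction, plus GENE/EFF/PCH/HCH/DRV after annotation. The FILTER
column carries the pipeline's flag names verbatim.
"""
from __future__ import annotations

import pysam

from .dualpool_caller import FILTER_FLAGS, ConsensusVariant
from .panel_model import PanelDesign
from .variant_filters import PanelOfNormals

_INFO_LINES = [
    ('DPA', 1, 'Integer', 'Pool A depth'),
    ('DPB', 1, 'Integer', 'Pool B depth'),
    ('ADA', 1, 'Integer', 'Pool A alt read count'),
    ('ADB', 1, 'Integer', 'Pool B alt read count'),
    ('CVAF', 1, 'Float', 'Merged (cumulative) variant allele fraction'),
    ('GENE', 1, 'String', 'Gene symbol'),
    ('EFF', 1, 'String', 'Effect class'),
    ('PCH', 1, 'String', 'Protein change (canine coordinates)'),
    ('HCH', 1, 'String', 'Protein change mapped to the human homolog'),
    ('DRV', 1, 'String', 'Driver status'),
]

_FILTER_DESC = {
    'single_pool': 'Called in only one of the two mirrored pools',
    'low_depth': 'Cumulative depth below 1000X (mean per pool below 500X)',
    'low_vaf': 'Merged allele fraction not above 3%',
    'in_normals': 'Present in the panel of normals',
    'effect_excluded': 'Synonymous, intronic or UTR (non-splice) variant',
}


def _header(panel: PanelDesign) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in sorted(panel.reference or {}):
        header.contigs.add(chrom, length=len(panel.reference[chrom]))
    for flag in FILTER_FLAGS:
        header.filters.add(flag, None, None, _FILTER_DESC[flag])
    for name, number, vtype, desc in _INFO_LINES:
        header.info.add(name, number, vtype, desc)
    return header


def write_sample_vcf(variants: list[ConsensusVariant], panel: PanelDesign,
                     path) -> None:
    header = _header(panel)
    with pysam.VariantFile(str(path), 'w', header=header) as vcf:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            rec = vcf.new_record(contig=v.chrom, start=v.pos - 1,
                                 alleles=(v.ref, v.alt))
            ev = v.pool_evidence
            rec.info['DPA'], rec.info['ADA'] = ev['A'][0], ev['A'][1]
            rec.info['DPB'], rec.info['ADB'] = ev.get('B', (0, 0, 0.0))[0], \
                ev.get('B', (0, 0, 0.0))[1]
            rec.info['CVAF'] = v.merged_vaf
            for attr, key in (('gene', 'GENE'), ('effect', 'EFF')):
                val = getattr(v, attr, None)
                if val:
                    rec.info[key] = val
            change = getattr(v, 'protein_change', None)
            if change is not None:
                rec.info['PCH'] = str(change)
            human = getattr(v, 'human_change', None)
            if human:
                rec.info['HCH'] = human
            status = getattr(v, 'driver_status', None)
            if status and status != 'none':
                rec.info['DRV'] = status
            if v.filter_flags:
                for flag in sorted(v.filter_flags):
                    rec.filter.add(flag)
            else:
                rec.filter.add('PASS')
            vcf.write(rec)


def read_sample_vcf(path, sample_id: str) -> list[ConsensusVariant]:
    """Rehydrate consensus records (with any annotation INFO) from a VCF."""
    from .annotation import AnnotatedVariant
    from .effects import parse_protein_change
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            dpa, ada = int(info['DPA']), int(info['ADA'])
            dpb, adb = int(info['DPB']), int(info['ADB'])
            flags = {f for f in rec.filter.keys() if f != 'PASS'}
            called = {'A', 'B'} - ({'A'} if 'single_pool' in flags and ada == 0 else
                                   {'B'} if 'single_pool' in flags and adb == 0 else set())
            v = AnnotatedVariant(
                sample_id=sample_id, chrom=rec.chrom, pos=rec.pos,
                ref=rec.ref, alt=rec.alts[0],
                pool_evidence={'A': (dpa, ada, ada / dpa if dpa else 0.0),
                               'B': (dpb, adb, adb / dpb if dpb else 0.0)},
                called_pools=frozenset(called), filter_flags=flags,
                gene=info.get('GENE'), effect=info.get('EFF'),
                protein_change=(parse_protein_change(info['PCH'])
                                if 'PCH' in info else None),
                human_change=info.get('HCH'),
                driver_status=info.get('DRV', 'none'))
            out.append(v)
    return out


def write_pon_vcf(pon: PanelOfNormals, panel: PanelDesign, path) -> None:
    """Persist the panel of normals as a sites-only VCF."""
    header = _header(panel)
    header.add_meta('pon_n_samples', str(pon.n_samples))
    with pysam.VariantFile(str(path), 'w', header=header) as vcf:
        for chrom, pos, ref, alt in sorted(pon.entries):
            rec = vcf.new_record(contig=chrom, start=pos - 1, alleles=(ref, alt))
            rec.filter.add('PASS')
            vcf.write(rec)


def read_pon_vcf(path) -> PanelOfNormals:
    entries = set()
    n_samples = 0
    with pysam.VariantFile(str(path)) as vcf:
        for line in str(vcf.header).splitlines():
            if line.startswith('##pon_n_samples='):
                n_samples = int(line.split('=', 1)[1])
        for rec in vcf:
            entries.add((rec.chrom, rec.pos, rec.ref, rec.alts[0]))
    return PanelOfNormals(entries=entries, n_samples=n_samples)
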