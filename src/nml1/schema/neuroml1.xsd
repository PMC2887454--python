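<?xml version="1.0" encoding="UTF-8"?>
<!--
  Structural envelope of the NeuroML v1.x dialect emitted by this package.
  The schema fixes the root element, its attributes and the set of legal
  top-level containers; deeper content is checked by the semantic
  validator, and elements from other namespaces (annotations, proprietary
  extensions) are admitted and preserved opaquely.
-->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns:nml="http://morphml.org/neuroml/schema"
           targetNamespace="http://morphml.org/neuroml/schema"
           elementFormDefault="qualified">

  <xs:complexType name="Opaque" mixed="true">
    <xs:sequence>
      <xs:any processContents="skip" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:anyAttribute processContents="skip"/>
  </xs:complexType>

  <xs:element name="neuroml">
    <xs:complexType>
      <xs:choice minOccurs="0" maxOccurs="unbounded">
        <xs:element name="notes" type="nml:Opaque"/>
        <xs:element name="authors" type="nml:Opaque"/>
        <xs:element name="translators" type="nml:Opaque"/>
        <xs:element name="publications" type="nml:Opaque"/>
        <xs:element name="database_refs" type="nml:Opaque"/>
        <xs:element name="status" type="nml:Opaque"/>
        <xs:element name="cells" type="nml:Opaque"/>
        <xs:element name="channels" type="nml:Opaque"/>
        <xs:element name="synapses" type="nml:Opaque"/>
        <xs:element name="network" type="nml:Opaque"/>
        <xs:any namespace="##other" processContents="lax"/>
      </xs:choice>
      <xs:attribute name="units">
        <xs:simpleType>
          <xs:restriction base="xs:string">
            <xs:enumeration value="SI Units"/>
            <xs:enumeration value="Physiological Units"/>
          </xs:restriction>
        </xs:simpleType>
      </xs:attribute>
      <xs:attribute name="level">
        <xs:simpleType>
          <xs:restriction base="xs:integer">
            <xs:minInclusive value="1"/>
            <xs:maxInclusive value="3"/>
          </xs:restriction>
        </xs:simpleType>
      </xs:attribute>
      <xs:attribute name="schema_version" type="xs:string"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
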