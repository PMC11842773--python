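<?xml version="1.0" encoding="UTF-8"?>
<!--
  Synthetic reduced schema for EML 2.2 documents as read and written by
  unitlink. It mirrors the element order of the official EML 2.2 attribute
  model (annotation elements come last inside an attribute) but covers only
  the subset of EML used by this package's fixtures; it is NOT the official
  EML schema distribution.
-->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns:eml="https://eml.ecoinformatics.org/eml-2.2.0"
           targetNamespace="https://eml.ecoinformatics.org/eml-2.2.0"
           elementFormDefault="unqualified">

  <xs:element name="eml">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="dataset" type="eml:DatasetType"/>
      </xs:sequence>
      <xs:attribute name="packageId" type="xs:string"/>
      <xs:attribute name="system" type="xs:string"/>
    </xs:complexType>
  </xs:element>

  <xs:complexType name="DatasetType">
    <xs:sequence>
      <xs:element name="title" type="xs:string" minOccurs="0"/>
      <xs:element name="creator" type="eml:PersonType" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="contact" type="eml:PersonType" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="dataTable" type="eml:DataTableType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="PersonType">
    <xs:sequence>
      <xs:element name="individualName" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="givenName" type="xs:string" minOccurs="0"/>
            <xs:element name="surName" type="xs:string"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="organizationName" type="xs:string" minOccurs="0"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="DataTableType">
    <xs:sequence>
      <xs:element name="entityName" type="xs:string" minOccurs="0"/>
      <xs:element name="entityDescription" type="xs:string" minOccurs="0"/>
      <xs:element name="attributeList">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="attribute" type="eml:AttributeType" maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="AttributeType">
    <xs:sequence>
      <xs:element name="attributeName" type="xs:string"/>
      <xs:element name="attributeDefinition" type="xs:string" minOccurs="0"/>
      <xs:element name="measurementScale" minOccurs="0">
        <xs:complexType>
          <xs:choice>
            <xs:element name="ratio" type="eml:NumericScaleType"/>
            <xs:element name="interval" type="eml:NumericScaleType"/>
            <xs:element name="nominal" type="eml:NominalScaleType"/>
          </xs:choice>
        </xs:complexType>
      </xs:element>
      <xs:element name="annotation" type="eml:AnnotationType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:string"/>
  </xs:complexType>

  <xs:complexType name="NumericScaleType">
    <xs:sequence>
      <xs:element name="unit">
        <xs:complexType>
          <xs:choice>
            <xs:element name="standardUnit" type="xs:string"/>
            <xs:element name="customUnit" type="xs:string"/>
          </xs:choice>
        </xs:complexType>
      </xs:element>
      <xs:element name="numericDomain" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="numberType" type="xs:string"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="NominalScaleType">
    <xs:sequence>
      <xs:element name="nonNumericDomain" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="textDomain" minOccurs="0">
              <xs:complexType>
                <xs:sequence>
                  <xs:element name="definition" type="xs:string"/>
                </xs:sequence>
              </xs:complexType>
            </xs:element>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="AnnotationType">
    <xs:sequence>
      <xs:element name="propertyURI" type="eml:LabelledUriType"/>
      <xs:element name="valueURI" type="eml:LabelledUriType"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="LabelledUriType">
    <xs:simpleContent>
      <xs:extension base="xs:anyURI">
        <xs:attribute name="label" type="xs:string" use="required"/>
      </xs:extension>
    </xs:simpleContent>
  </xs:complexType>

</xs:schema>
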